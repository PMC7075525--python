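"""Distance-constraint (DisCo) scoring.

Homologous template structures are mapped onto the target sequence; every
template Calpha–Calpha distance mu_ijk below 15 A becomes a unit-width
Gaussian constraint

    g_ijk(d) = exp[-1/2 (d - mu_ijk)^2].

Templates are clustered by pairwise sequence similarity to suppress
over-represented families.  For each residue pair covered by a cluster c
the cluster scoring function is the mean of its member constraints,

    h_ijc(d) = 1/n_ijc sum_{k in c} g_ijk(d),

and the pairwise scoring function combines clusters weighted by their
average normalized sequence similarity to the target,

    s_ij(d) = sum_c w_c h_ijc(d),   w_c prop. exp(gamma * SS_c),

with the weights normalized over the clusters actually covering (i, j).
The per-residue DisCo score averages s_ij(d_ij) over all residues j with
model Calpha within 15 A for which constraints exist, and seven
reliability features describe how well the ensemble supports each residue.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from Bio.Align import substitution_matrices

from .structure import Structure, read_pdb

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_MIN = float(np.min(_BLOSUM62))

DISCO_RADIUS = 15.0
DEFAULT_GAMMA = 70.0
DEFAULT_CLUSTER_THRESHOLD = 0.8


def _blosum(a: str, b: str) -> float | None:
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return None


def _column_similarity(a: str, b: str) -> float | None:
    """BLOSUM62 column score rescaled so identity -> 1, matrix minimum -> 0."""
    raw = _blosum(a, b)
    if raw is None:
        return None
    self_ref = 0.5 * ((_blosum(a, a) or 4.0) + (_blosum(b, b) or 4.0))
    denom = self_ref - _BLOSUM_MIN
    return float(np.clip((raw - _BLOSUM_MIN) / denom, 0.0, 1.0))


def normalized_similarity(pairs) -> float:
    """Mean per-aligned-column normalized BLOSUM62 score over residue pairs."""
    scores = [s for a, b in pairs if (s := _column_similarity(a, b)) is not None]
    return float(np.mean(scores)) if scores else 0.0


@dataclass
class AlignedTemplate:
    template_id: str
    target_to_template: dict           # target residue index -> template index
    template_sequence: str
    ca_coordinates: dict               # template residue index -> (3,) array
    seq_similarity: float
    seq_identity: float


def parse_a3m(path) -> list:
    """(id, sequence) records of an A3M/FASTA alignment, first = master."""
    records = []
    header, seq = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(seq)))
                header = line[1:].split()[0]
                seq = []
            elif line:
                seq.append(line)
    if header is not None:
        records.append((header, "".join(seq)))
    if not records:
        raise ValueError(f"{path}: empty alignment")
    return records


def _map_template(target_seq: str, aligned: str) -> tuple[dict, str]:
    """A3M convention: uppercase/'-' consume one target (match) column,
    lowercase letters are template insertions and consume none.  Returns
    (target index -> template index, ungapped template sequence)."""
    mapping = {}
    t_idx = 0       # target match column
    k_idx = 0       # template residue counter
    tpl_seq = []
    for ch in aligned:
        if ch == "-":
            t_idx += 1
        elif ch.islower():
            tpl_seq.append(ch.upper())
            k_idx += 1
        else:
            if t_idx < len(target_seq) and ch != "X":
                mapping[t_idx] = k_idx
            tpl_seq.append(ch)
            t_idx += 1
            k_idx += 1
    return mapping, "".join(tpl_seq)


def load_alignments(a3m_path, template_dir) -> tuple[str, list]:
    """Read an A3M alignment (first sequence = target) and attach template
    Calpha coordinates from ``template_dir/<template_id>.pdb``.

    Returns (target sequence, list of AlignedTemplate).  Unresolvable
    templates are skipped with a warning.
    """
    import logging

    records = parse_a3m(a3m_path)
    target_id, target_aligned = records[0]
    target_seq = target_aligned.replace("-", "").upper()
    templates = []
    for tpl_id, aligned in records[1:]:
        pdb_candidates = glob.glob(os.path.join(str(template_dir),
                                                f"{tpl_id}.pdb"))
        if not pdb_candidates:
            logging.getLogger(__name__).warning(
                "template %s: no coordinate file, skipped", tpl_id)
            continue
        tpl_struct = read_pdb(pdb_candidates[0])
        mapping, tpl_seq = _map_template(target_seq, aligned)
        ca = {}
        for r in tpl_struct:
            if r.ca is not None:
                ca[r.index] = r.ca
        mapping = {t: k for t, k in mapping.items() if k in ca}
        aligned_cols = [(target_seq[t], tpl_seq[k])
                        for t, k in sorted(mapping.items()) if k < len(tpl_seq)]
        identity = (
            sum(a == b for a, b in aligned_cols) / len(aligned_cols)
            if aligned_cols else 0.0
        )
        templates.append(AlignedTemplate(
            template_id=tpl_id,
            target_to_template=mapping,
            template_sequence=tpl_seq,
            ca_coordinates=ca,
            seq_similarity=normalized_similarity(aligned_cols),
            seq_identity=identity,
        ))
    return target_seq, templates


@dataclass
class TemplateCluster:
    members: list
    avg_seq_similarity: float    # SS_c
    avg_seq_identity: float


def template_pair_similarity(a: AlignedTemplate, b: AlignedTemplate) -> float:
    """Similarity between two templates over target columns mapped in both."""
    shared = sorted(set(a.target_to_template) & set(b.target_to_template))
    pairs = []
    for t in shared:
        ka, kb = a.target_to_template[t], b.target_to_template[t]
        if ka < len(a.template_sequence) and kb < len(b.template_sequence):
            pairs.append((a.template_sequence[ka], b.template_sequence[kb]))
    if not pairs:
        return 0.0
    return normalized_similarity(pairs)


def cluster_templates(templates,
                      similarity_threshold: float = DEFAULT_CLUSTER_THRESHOLD
                      ) -> list:
    """Average-linkage agglomerative clustering on 1 - pairwise similarity,
    cut so that templates above the similarity threshold share a cluster.
    Deterministic: templates are ordered by id before clustering."""
    if not templates:
        raise ValueError("at least one template required")
    templates = sorted(templates, key=lambda t: t.template_id)
    n = len(templates)
    if n == 1:
        labels = np.array([1])
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - template_pair_similarity(templates[i], templates[j])
                dist[i, j] = dist[j, i] = d
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=1.0 - similarity_threshold,
                          criterion="distance")
    clusters = []
    for lab in sorted(set(labels)):
        members = [templates[i] for i in range(n) if labels[i] == lab]
        clusters.append(TemplateCluster(
            members=members,
            avg_seq_similarity=float(np.mean(
                [m.seq_similarity for m in members])),
            avg_seq_identity=float(np.mean(
                [m.seq_identity for m in members])),
        ))
    return clusters


@dataclass
class ConstraintEnsemble:
    target_length: int
    gamma: float
    cluster_ss: np.ndarray             # SS_c per cluster
    cluster_identity: np.ndarray
    pairs: dict = field(repr=False)    # (i, j) -> {cluster index: mu array}


def build_ensemble(clusters, target_length: int,
                   gamma: float = DEFAULT_GAMMA) -> ConstraintEnsemble:
    """Collect all template Calpha–Calpha distances below 15 A per target
    residue pair, grouped by cluster."""
    pairs: dict = {}
    for c_idx, cluster in enumerate(clusters):
        for tpl in cluster.members:
            items = sorted(tpl.target_to_template.items())
            t_idx = np.array([t for t, _ in items], dtype=int)
            coords = np.array([tpl.ca_coordinates[k] for _, k in items])
            if len(t_idx) < 2:
                continue
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            iu, ju = np.triu_indices(len(t_idx), k=1)
            keep = d[iu, ju] < DISCO_RADIUS
            for a, b, mu in zip(iu[keep], ju[keep], d[iu, ju][keep]):
                key = (int(t_idx[a]), int(t_idx[b]))
                pairs.setdefault(key, {}).setdefault(c_idx, []).append(
                    float(mu))
    for key, by_cluster in pairs.items():
        for c_idx in by_cluster:
            by_cluster[c_idx] = np.asarray(by_cluster[c_idx])
    return ConstraintEnsemble(
        target_length=target_length,
        gamma=gamma,
        cluster_ss=np.array([c.avg_seq_similarity for c in clusters]),
        cluster_identity=np.array([c.avg_seq_identity for c in clusters]),
        pairs=pairs,
    )


def evaluate_pair(ensemble: ConstraintEnsemble, i: int, j: int,
                  d_ij: float):
    """s_ij(d_ij), or None when the pair carries no constraints."""
    key = (i, j) if i < j else (j, i)
    by_cluster = ensemble.pairs.get(key)
    if not by_cluster:
        return None
    c_idx = np.array(sorted(by_cluster))
    ss = ensemble.cluster_ss[c_idx]
    w = np.exp(ensemble.gamma * (ss - ss.max()))  # stable softmax weights
    w /= w.sum()
    h = np.array([
        float(np.mean(np.exp(-0.5 * (d_ij - by_cluster[c]) ** 2)))
        for c in c_idx
    ])
    return float(np.dot(w, h))


@dataclass
class DisCoResult:
    disco: np.ndarray                  # NaN where no evaluated pairs
    avg_n_clusters: np.ndarray
    avg_max_seq_similarity: np.ndarray
    avg_max_seq_identity: np.ndarray
    avg_variance: np.ndarray
    n_evaluated_pairs: np.ndarray
    n_total_pairs: np.ndarray
    fraction_evaluated: np.ndarray

    def feature_matrix(self) -> np.ndarray:
        """(n, 8) matrix: score followed by the seven reliability features."""
        return np.column_stack([
            self.disco, self.avg_n_clusters, self.avg_max_seq_similarity,
            self.avg_max_seq_identity, self.avg_variance,
            self.n_evaluated_pairs, self.n_total_pairs,
            self.fraction_evaluated,
        ])


def score_model(ensemble: ConstraintEnsemble, model: Structure) -> DisCoResult:
    """Per-residue DisCo score of *model* plus reliability features.

    All residue pairs with model Calpha distance below 15 A count towards
    ``n_total_pairs``; only those covered by at least one constraint are
    evaluated.
    """
    if len(model) != ensemble.target_length:
        raise ValueError("model length does not match ensemble target length")
    n = len(model)
    ca = model.ca_array()
    disco = np.full(n, np.nan)
    avg_nc = np.full(n, np.nan)
    avg_ss = np.full(n, np.nan)
    avg_id = np.full(n, np.nan)
    avg_var = np.full(n, np.nan)
    n_eval = np.zeros(n)
    n_total = np.zeros(n)

    valid = ~np.isnan(ca[:, 0])
    idx = np.flatnonzero(valid)
    d = np.linalg.norm(ca[idx, None] - ca[None, idx], axis=-1)
    for a_pos, i in enumerate(idx):
        scores, ncs, sss, ids, variances = [], [], [], [], []
        for b_pos, j in enumerate(idx):
            if i == j or d[a_pos, b_pos] >= DISCO_RADIUS:
                continue
            n_total[i] += 1
            s = evaluate_pair(ensemble, int(i), int(j), d[a_pos, b_pos])
            if s is None:
                continue
            key = (int(i), int(j)) if i < j else (int(j), int(i))
            by_cluster = ensemble.pairs[key]
            c_idx = np.array(sorted(by_cluster))
            scores.append(s)
            ncs.append(len(c_idx))
            sss.append(float(ensemble.cluster_ss[c_idx].max()))
            ids.append(float(ensemble.cluster_identity[c_idx].max()))
            pooled = np.concatenate([by_cluster[c] for c in c_idx])
            variances.append(float(np.var(pooled)))
        if scores:
            disco[i] = float(np.mean(scores))
            avg_nc[i] = float(np.mean(ncs))
            avg_ss[i] = float(np.mean(sss))
            avg_id[i] = float(np.mean(ids))
            avg_var[i] = float(np.mean(variances))
            n_eval[i] = len(scores)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(n_total > 0, n_eval / np.maximum(n_total, 1), 0.0)
    return DisCoResult(disco, avg_nc, avg_ss, avg_id, avg_var,
                       n_eval, n_total, fraction)


def ensemble_from_files(a3m_path, template_dir,
                        gamma: float = DEFAULT_GAMMA,
                        similarity_threshold: float =
                        DEFAULT_CLUSTER_THRESHOLD) -> ConstraintEnsemble:
    """Convenience: alignment file + template directory -> ensemble."""
    target_seq, templates = load_alignments(a3m_path, template_dir)
    if not templates:
        raise ValueError("no usable templates in alignment")
    clusters = cluster_templates(templates, similarity_threshold)
    return build_ensemble(clusters, len(target_seq), gamma)
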
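"""End-to-end orchestration: checkpoints, feature computation, dataset
construction, training and scoring.

A *checkpoint directory* holds everything a scoring run needs: the six
trained potential tables, the secondary-structure agreement table, the
neural-network scorer and (optionally) the expected-error model.  Missing
optional inputs at scoring time (no alignment, no predictor files) simply
invalidate the corresponding feature blocks; the NNScorer dispatches those
residues to the matching reduced network instead of failing.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import dataclass

import numpy as np

from . import disco as disco_mod
from .global_score import ErrorModel, GlobalResult, summarize
from .lddt import LddtParams, compute_lddt
from .local_features import (SSAgreementTable, acc_agreement,
                             assign_secondary_structure, clash_score,
                             read_accpro, read_psipred_ss2,
                             relative_accessibility, residue_count,
                             solvent_accessibility, ss_agreement)
from .nnscorer import NNScorer, ResidueDataset, assemble_features
from .potentials import TERMS, StatisticalPotential, score_all_terms
from .structure import Residue, Structure, extract_sequence
from .synth import (SyntheticScenario, TargetBundle, make_target_bundle,
                    make_training_corpus, mapping_by_number)


class MissingCheckpoint(FileNotFoundError):
    """A required trained component is absent from the checkpoint dir."""


@dataclass
class Checkpoints:
    potentials: dict                     # term -> StatisticalPotential
    ss_table: SSAgreementTable
    scorer: NNScorer
    error_model: ErrorModel | None = None

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        for term, pot in self.potentials.items():
            pot.to_npz(os.path.join(directory, f"potential_{term}.npz"))
        with open(os.path.join(directory, "ss_table.json"), "w") as fh:
            json.dump(self.ss_table.to_dict(), fh)
        self.scorer.save(os.path.join(directory, "nnscorer.json"))
        if self.error_model is not None:
            with open(os.path.join(directory, "error_model.json"),
                      "w") as fh:
                json.dump(self.error_model.to_dict(), fh)

    @classmethod
    def load(cls, directory) -> "Checkpoints":
        potentials = {}
        for term in TERMS:
            path = os.path.join(directory, f"potential_{term}.npz")
            if not os.path.exists(path):
                raise MissingCheckpoint(f"missing potential table: {path}")
            potentials[term] = StatisticalPotential.from_npz(path)
        ss_path = os.path.join(directory, "ss_table.json")
        nn_path = os.path.join(directory, "nnscorer.json")
        if not os.path.exists(ss_path):
            raise MissingCheckpoint(f"missing SS agreement table: {ss_path}")
        if not os.path.exists(nn_path):
            raise MissingCheckpoint(f"missing NN scorer: {nn_path}")
        with open(ss_path) as fh:
            ss_table = SSAgreementTable.from_dict(json.load(fh))
        scorer = NNScorer.load(nn_path)
        err_path = os.path.join(directory, "error_model.json")
        error_model = None
        if os.path.exists(err_path):
            with open(err_path) as fh:
                error_model = ErrorModel.from_dict(json.load(fh))
        return cls(potentials, ss_table, scorer, error_model)


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------

def _padded_to_target(model: Structure, target_map: dict,
                      target_length: int) -> Structure:
    """Model re-indexed on the target sequence (empty residues where the
    model does not cover the target); used for DisCo scoring."""
    by_target = {t: model[m] for m, t in target_map.items()}
    residues = []
    for t in range(target_length):
        src = by_target.get(t)
        if src is None:
            residues.append(Residue(t, t + 1, "", "X", {}))
        else:
            residues.append(Residue(t, t + 1, "", src.aa, src.atoms))
    return Structure(model.id, residues)


def compute_features(model: Structure, checkpoints: Checkpoints,
                     psipred=None, accpro=None,
                     ensemble=None, target_map: dict | None = None
                     ) -> np.ndarray:
    """(n_residues, 47) NaN-masked feature matrix for one model.

    *psipred* / *accpro* are predictor outputs indexed on the target
    sequence; *target_map* maps model residue index -> target index and
    defaults to the identity.
    """
    n = len(model)
    if target_map is None:
        target_map = {i: i for i in range(n)}
    seq = extract_sequence(model)
    pot_scores = score_all_terms(checkpoints.potentials, model)
    dssp = assign_secondary_structure(model)
    asa = solvent_accessibility(model)
    rel = relative_accessibility(asa, seq)
    clash = clash_score(model)
    n_count = residue_count(model)

    ss_agr = None
    if psipred is not None:
        ss_agr = np.full(n, np.nan)
        for i in range(n):
            t = target_map.get(i)
            if t is not None and t < len(psipred):
                state, conf = psipred[t]
                ss_agr[i] = checkpoints.ss_table.score(dssp[i], state, conf)
    acc_agr = None
    if accpro is not None:
        states = [accpro[target_map[i]] if target_map.get(i) is not None
                  and target_map[i] < len(accpro) else "e" for i in range(n)]
        acc_agr = acc_agreement(asa, seq, states)

    disco_result = None
    if ensemble is not None:
        padded = _padded_to_target(model, target_map,
                                   ensemble.target_length)
        full = disco_mod.score_model(ensemble, padded)
        rows = np.array([target_map[i] for i in range(n)])
        disco_result = disco_mod.DisCoResult(
            *(getattr(full, f)[rows] for f in (
                "disco", "avg_n_clusters", "avg_max_seq_similarity",
                "avg_max_seq_identity", "avg_variance",
                "n_evaluated_pairs", "n_total_pairs",
                "fraction_evaluated"))
        )

    return assemble_features(
        model, pot_scores, ss_agreement=ss_agr, acc_agreement=acc_agr,
        rel_accessibility=rel, clash=clash, residue_n=n_count,
        disco_result=disco_result,
    )


# ---------------------------------------------------------------------------
# Training on synthetic bundles
# ---------------------------------------------------------------------------

def make_bundles(n_targets: int, seed: int, out_dir,
                 length_range=(35, 55)) -> list:
    """Generate *n_targets* synthetic modelling targets under *out_dir*."""
    rng = np.random.default_rng(seed)
    bundles = []
    for k in range(n_targets):
        scen = SyntheticScenario(
            seed=int(rng.integers(2 ** 31)),
            length=int(rng.integers(*length_range)),
        )
        target_dir = os.path.join(str(out_dir), f"target_{k:03d}")
        os.makedirs(target_dir, exist_ok=True)
        bundles.append(make_target_bundle(scen, target_dir))
    return bundles


def train_ss_table(bundles, pseudo_count: float = 1.0) -> SSAgreementTable:
    """Train the DSSP/PSIPRED log-odds table on native structures paired
    with their (mock) predictions."""
    observations = []
    for b in bundles:
        dssp = assign_secondary_structure(b.native)
        psipred = read_psipred_ss2(b.ss2_path)
        for d, (p, c) in zip(dssp, psipred):
            observations.append((d, p, c))
    return SSAgreementTable(pseudo_count=pseudo_count).fit(observations)


def build_dataset(bundles, checkpoints: Checkpoints,
                  lddt_params: LddtParams | None = None) -> ResidueDataset:
    """Feature rows + lDDT targets for every model of every bundle."""
    xs, ys, t_ids, m_ids = [], [], [], []
    for b in bundles:
        psipred = read_psipred_ss2(b.ss2_path)
        accpro = read_accpro(b.acc_path)
        ensemble = disco_mod.ensemble_from_files(b.a3m_path, b.template_dir)
        for model in b.models:
            tmap = mapping_by_number(model, b.native)
            X = compute_features(model, checkpoints, psipred=psipred,
                                 accpro=accpro, ensemble=ensemble,
                                 target_map=tmap)
            res = compute_lddt(model, b.native, mapping=tmap,
                               params=lddt_params)
            y = np.array([res.per_residue[tmap[i]] if i in tmap else np.nan
                          for i in range(len(model))])
            xs.append(X)
            ys.append(y)
            t_ids.append(np.repeat(b.native.id, len(model)))
            m_ids.append(np.repeat(model.id, len(model)))
    return ResidueDataset(
        X=np.concatenate(xs), y=np.concatenate(ys),
        target_ids=np.concatenate(t_ids), model_ids=np.concatenate(m_ids),
    )


def train_checkpoints(bundles, seed: int, corpus_size: int = 150,
                      **scorer_params) -> Checkpoints:
    """Train all components on synthetic data: potential tables on a
    corpus of clash-free natives, the SS table on native/prediction pairs
    and the NNScorer on the bundles' models."""
    corpus = make_training_corpus(corpus_size, seed=seed % (2 ** 31))
    corpus += [b.native for b in bundles]
    potentials = {
        term: StatisticalPotential(term=term).fit(corpus) for term in TERMS
    }
    ss_table = train_ss_table(bundles)
    partial = Checkpoints(potentials, ss_table, scorer=None)
    dataset = build_dataset(bundles, partial)
    scorer = NNScorer(seed=seed % (2 ** 31), **scorer_params)
    scorer.fit(dataset.X, dataset.y)
    return Checkpoints(potentials, ss_table, scorer), dataset


# ---------------------------------------------------------------------------
# End-to-end scoring
# ---------------------------------------------------------------------------

@dataclass
class QualityResult:
    model_id: str
    mode: str                           # "full" or "single-model"
    per_residue: np.ndarray
    global_result: GlobalResult
    reference_lddt: np.ndarray | None = None

    def to_dict(self) -> dict:
        g = self.global_result
        out = {
            "model": self.model_id,
            "mode": self.mode,
            "global_score": g.global_score,
            "coverage": g.coverage,
            "normalized_score": g.normalized_score,
            "expected_error": g.expected_error,
            "model_length": g.model_length,
            "per_residue": [None if not np.isfinite(v) else round(float(v), 6)
                            for v in self.per_residue],
        }
        if self.reference_lddt is not None:
            out["reference_lddt"] = [
                None if not np.isfinite(v) else round(float(v), 6)
                for v in self.reference_lddt]
        return out


def score_structure(model: Structure, checkpoints: Checkpoints,
                    target_sequence: str | None = None,
                    psipred=None, accpro=None, ensemble=None,
                    target_map: dict | None = None,
                    reference: Structure | None = None) -> QualityResult:
    """Run the full scoring pipeline on one model."""
    if target_sequence is None:
        target_sequence = extract_sequence(model)
    X = compute_features(model, checkpoints, psipred=psipred, accpro=accpro,
                         ensemble=ensemble, target_map=target_map)
    preds = checkpoints.scorer.predict(X)
    global_result = summarize(preds, model, target_sequence,
                              error_model=checkpoints.error_model)
    ref_lddt = None
    if reference is not None:
        res = compute_lddt(model, reference)
        ref_lddt = np.array([
            res.per_residue[i] if i < len(res.per_residue) else np.nan
            for i in range(len(model))])
    return QualityResult(
        model_id=model.id,
        mode="full" if ensemble is not None else "single-model",
        per_residue=preds,
        global_result=global_result,
        reference_lddt=ref_lddt,
    )


# ---------------------------------------------------------------------------
# Fixture-tree persistence (make-fixtures / train-nn CLI)
# ---------------------------------------------------------------------------

def write_fixture_tree(bundles, out_dir) -> None:
    from .structure import write_pdb

    for sub in ("natives", "models", "alignments", "templates",
                "predictions"):
        os.makedirs(os.path.join(str(out_dir), sub), exist_ok=True)
    for b in bundles:
        tid = b.native.id
        write_pdb(b.native, os.path.join(str(out_dir), "natives",
                                         f"{tid}.pdb"))
        mdir = os.path.join(str(out_dir), "models", tid)
        os.makedirs(mdir, exist_ok=True)
        for m in b.models:
            write_pdb(m, os.path.join(mdir, f"{m.id}.pdb"))
        import shutil
        shutil.copy(b.a3m_path, os.path.join(str(out_dir), "alignments",
                                             f"{tid}.a3m"))
        tdir = os.path.join(str(out_dir), "templates", tid)
        os.makedirs(tdir, exist_ok=True)
        for tpl in glob.glob(os.path.join(b.template_dir, "*.pdb")):
            shutil.copy(tpl, tdir)
        shutil.copy(b.ss2_path, os.path.join(str(out_dir), "predictions",
                                             f"{tid}.ss2"))
        shutil.copy(b.acc_path, os.path.join(str(out_dir), "predictions",
                                             f"{tid}.acc"))


def read_fixture_tree(root) -> list:
    """Reload a make-fixtures directory into TargetBundle objects."""
    from .structure import read_pdb

    bundles = []
    for native_path in sorted(glob.glob(os.path.join(str(root), "natives",
                                                     "*.pdb"))):
        tid = os.path.splitext(os.path.basename(native_path))[0]
        native = read_pdb(native_path)
        native.id = tid
        models = []
        for mp in sorted(glob.glob(os.path.join(str(root), "models", tid,
                                                "*.pdb"))):
            m = read_pdb(mp)
            m.id = os.path.splitext(os.path.basename(mp))[0]
            models.append(m)
        bundles.append(TargetBundle(
            scenario=None, native=native, models=models,
            a3m_path=os.path.join(str(root), "alignments", f"{tid}.a3m"),
            template_dir=os.path.join(str(root), "templates", tid),
            ss2_path=os.path.join(str(root), "predictions", f"{tid}.ss2"),
            acc_path=os.path.join(str(root), "predictions", f"{tid}.acc"),
        ))
    return bundles
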
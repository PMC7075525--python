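"""Local Distance Difference Test (lDDT).

Superposition-free model accuracy score: every heavy-atom pair of the
reference structure within the inclusion radius (and belonging to different
residues) defines one check per deviation threshold; a check is conserved
when the corresponding model distance deviates by less than the threshold.
Per-residue scores pool the checks touching a residue's atoms, the global
score pools all checks (it is *not* the mean of per-residue values, so
incomplete models are penalised coherently).

Atoms absent from the model fail their checks; atoms present only in the
model are ignored — wrong geometry is penalised, extra compactness is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Structure

_BACKBONE_SET = frozenset(["N", "CA", "C", "O", "CB"])


@dataclass
class LddtParams:
    inclusion_radius: float = 15.0
    thresholds: tuple = (0.5, 1.0, 2.0, 4.0)

    def __post_init__(self):
        th = tuple(self.thresholds)
        if any(t <= 0 for t in th) or any(
            a >= b for a, b in zip(th, th[1:])
        ):
            raise ValueError("thresholds must be strictly increasing and > 0")
        if self.inclusion_radius <= max(th):
            raise ValueError("inclusion radius must exceed all thresholds")
        self.thresholds = th


@dataclass
class LddtResult:
    per_residue: np.ndarray          # NaN where the residue has no checks
    global_score: float
    conserved: np.ndarray = field(repr=False, default=None)
    total: np.ndarray = field(repr=False, default=None)


def compute_lddt(model: Structure, reference: Structure,
                 mapping: dict | None = None,
                 params: LddtParams | None = None) -> LddtResult:
    """Per-residue and global lDDT of *model* against *reference*.

    ``mapping`` maps model residue index -> reference residue index and
    defaults to the identity over the shorter of the two ranges.  Scores are
    indexed on the reference residues.  Where the mapped residues disagree
    in amino-acid identity, only backbone + Cbeta atoms of that residue are
    compared.
    """
    params = params or LddtParams()
    if mapping is None:
        mapping = {i: i for i in range(min(len(model), len(reference)))}
    if not mapping:
        raise ValueError("empty model-to-reference mapping")

    ref_to_model = {v: k for k, v in mapping.items()}

    # Flatten reference atoms; keep a pointer to the matching model atom.
    ref_coords, ref_res, model_coords, has_model = [], [], [], []
    for r in reference:
        mi = ref_to_model.get(r.index)
        mres = model[mi] if mi is not None and mi < len(model) else None
        same_aa = mres is not None and mres.aa == r.aa
        for name, xyz in r.atoms.items():
            if mres is not None and not same_aa and name not in _BACKBONE_SET:
                continue
            ref_coords.append(xyz)
            ref_res.append(r.index)
            if mres is not None and name in mres.atoms:
                model_coords.append(mres.atoms[name])
                has_model.append(True)
            else:
                model_coords.append(np.zeros(3))
                has_model.append(False)
    if not ref_coords:
        raise ValueError("reference structure has no atoms")

    ref_coords = np.asarray(ref_coords)
    model_coords = np.asarray(model_coords)
    ref_res = np.asarray(ref_res)
    has_model = np.asarray(has_model)
    th = np.asarray(params.thresholds)

    n_res = len(reference)
    conserved = np.zeros(n_res)
    total = np.zeros(n_res)

    dref = np.linalg.norm(ref_coords[:, None, :] - ref_coords[None, :, :],
                          axis=-1)
    dmod = np.linalg.norm(model_coords[:, None, :] - model_coords[None, :, :],
                          axis=-1)
    n_atoms = len(ref_coords)
    iu, ju = np.triu_indices(n_atoms, k=1)
    pair_mask = (ref_res[iu] != ref_res[ju]) & (
        dref[iu, ju] < params.inclusion_radius
    )
    iu, ju = iu[pair_mask], ju[pair_mask]
    both = has_model[iu] & has_model[ju]
    dev = np.abs(dmod[iu, ju] - dref[iu, ju])
    n_cons = np.where(both, (dev[:, None] < th[None, :]).sum(axis=1), 0)

    np.add.at(total, ref_res[iu], len(th))
    np.add.at(total, ref_res[ju], len(th))
    np.add.at(conserved, ref_res[iu], n_cons)
    np.add.at(conserved, ref_res[ju], n_cons)

    with np.errstate(invalid="ignore", divide="ignore"):
        per_res = np.where(total > 0, conserved / total, np.nan)
    grand_total = total.sum() / 2  # each check counted once globally
    grand_cons = conserved.sum() / 2
    global_score = float(grand_cons / grand_total) if grand_total else np.nan
    return LddtResult(per_res, global_score, conserved, total)


def classify_correct(per_residue, cut: float = 0.6):
    """Binary 'correctly modelled' labels (score strictly above *cut*).

    Returns (labels, valid_mask); invalid scores (NaN) are excluded.
    """
    scores = np.asarray(per_residue, dtype=float)
    valid = ~np.isnan(scores)
    labels = (scores > cut).astype(int)
    return labels[valid], valid
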
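"""Non-potential single-model features.

* DSSP-equivalent 8-state secondary structure (Kabsch–Sander hydrogen-bond
  energy rule, bond when E < -0.5 kcal/mol) computed internally,
* Shrake–Rupley solvent-accessible surface per residue (probe 1.4 A,
  via biotite),
* secondary-structure agreement: trained log-odds score
  S(d, p, c) = log[p(d,p,c) / (p(d) p(p,c))] between the observed DSSP
  state d and the PSIPRED prediction (state p, confidence c),
* solvent-accessibility agreement with a two-state (buried/exposed)
  ACCpro-style prediction, burial cut at 25% relative accessibility,
* SCWRL3-style hard-sphere clash score,
* local residue count N (Calpha neighbours within 15 A),
* spherical Gaussian smoothing (sigma = 5 A) applied to per-residue traces.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

import biotite.structure as bst

from .constants import (CLASH_LINEAR_ONSET, CLASH_MAX_PENALTY, CLASH_RADII,
                        MAX_ASA, element_of)
from .structure import Structure, to_atom_array

DSSP_STATES = "GHIEBTSC"
PSIPRED_STATES = "HEC"
_HB_CUTOFF = -0.5      # kcal/mol
_HB_Q1Q2F = 0.084 * 332.0
_BURIAL_CUT = 0.25


# ---------------------------------------------------------------------------
# DSSP-equivalent secondary structure + accessibility
# ---------------------------------------------------------------------------

def _amide_hydrogens(s: Structure):
    """Backbone amide H positions, DSSP convention: 1.01 A from N opposite
    the previous residue's carbonyl O.  None for the N-terminus/prolines."""
    out = [None] * len(s)
    for i in range(1, len(s)):
        prev_r, r = s[i - 1], s[i]
        if r.aa == "P" or "N" not in r.atoms:
            continue
        if "C" not in prev_r.atoms or "O" not in prev_r.atoms:
            continue
        d = prev_r.atoms["C"] - prev_r.atoms["O"]
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        out[i] = r.atoms["N"] + 1.01 * d / norm
    return out


def _hbond_matrix(s: Structure) -> np.ndarray:
    """hb[a, d] True when the carbonyl of residue a accepts an H-bond from
    the amide of residue d (Kabsch–Sander electrostatic energy)."""
    n = len(s)
    hb = np.zeros((n, n), dtype=bool)
    hpos = _amide_hydrogens(s)
    for a in range(n):
        ra = s[a]
        if "C" not in ra.atoms or "O" not in ra.atoms:
            continue
        c, o = ra.atoms["C"], ra.atoms["O"]
        for d in range(n):
            if abs(d - a) < 1 or hpos[d] is None:
                continue
            nn = s[d].atoms.get("N")
            if nn is None:
                continue
            h = hpos[d]
            r_on = np.linalg.norm(o - nn)
            if r_on > 5.2:  # beyond any bonding distance, skip the rest
                continue
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - nn)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = _HB_Q1Q2F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            hb[a, d] = e < _HB_CUTOFF
    return hb


def assign_secondary_structure(s: Structure) -> list:
    """8-state DSSP-equivalent assignment (G/H/I/E/B/T/S/C).

    Implements the hydrogen-bond patterns for helices (3/4/5-turns),
    bridges/ladders, turns and bends; beta-bulge refinements of the full
    algorithm are not reproduced.
    """
    n = len(s)
    if n == 0:
        return []
    hb = _hbond_matrix(s)
    states = ["C"] * n

    def turn(i, k):
        return i + k < n and hb[i, i + k]

    # bends (lowest priority, assigned first then overwritten)
    ca = s.ca_array()
    for i in range(2, n - 2):
        if np.isnan(ca[[i - 2, i, i + 2], 0]).any():
            continue
        v1 = ca[i] - ca[i - 2]
        v2 = ca[i + 2] - ca[i]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            states[i] = "S"

    # turns
    for k in (3, 4, 5):
        for i in range(n):
            if turn(i, k):
                for j in range(i + 1, min(i + k, n)):
                    if states[j] in ("C", "S"):
                        states[j] = "T"

    # helices: two consecutive k-turns -> k-helix at i .. i+k-1
    for k, label in ((5, "I"), (3, "G"), (4, "H")):
        for i in range(1, n):
            if turn(i - 1, k) and turn(i, k):
                for j in range(i, min(i + k, n)):
                    states[j] = label

    # bridges and ladders
    bridge = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[j, i] and hb[i, j]) or (
                hb[i - 1, j] and hb[j, i + 1]) or (
                hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (
                hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                bridge[i, j] = bridge[j, i] = True
    for i in range(n):
        partners = np.flatnonzero(bridge[i])
        if partners.size == 0:
            continue
        extended = False
        for j in partners:
            for di in (-1, 1):
                ii = i + di
                if 0 <= ii < n and bridge[ii, max(0, j - 1):j + 2].any():
                    extended = True
        if extended:
            states[i] = "E"
        elif states[i] != "H":
            states[i] = "B"
    return states


def solvent_accessibility(s: Structure) -> np.ndarray:
    """Per-residue solvent-accessible surface area in A^2 (Shrake–Rupley,
    probe radius 1.4 A)."""
    array = to_atom_array(s)
    atom_sasa = bst.sasa(array, probe_radius=1.4, point_number=256)
    atom_sasa = np.nan_to_num(atom_sasa)
    out = np.zeros(len(s))
    i = 0
    for r in s:
        k = len(r.atoms)
        out[r.index] = atom_sasa[i:i + k].sum()
        i += k
    return out


def assign_ss_and_acc(s: Structure):
    """(DSSP-equivalent states, per-residue accessibility in A^2)."""
    return assign_secondary_structure(s), solvent_accessibility(s)


def relative_accessibility(asa: np.ndarray, sequence: str) -> np.ndarray:
    """Accessibility scaled to [0, 1] by per-residue theoretical maxima;
    NaN for residues without a known maximum."""
    out = np.full(len(sequence), np.nan)
    for i, aa in enumerate(sequence):
        mx = MAX_ASA.get(aa)
        if mx:
            out[i] = min(asa[i] / mx, 1.0)
    return out


# ---------------------------------------------------------------------------
# Agreement terms
# ---------------------------------------------------------------------------

class SSAgreementTable(BaseEstimator):
    """Log-odds agreement between observed DSSP states and PSIPRED
    predictions, trained from paired observations with Laplace smoothing."""

    def __init__(self, pseudo_count: float = 1.0):
        self.pseudo_count = pseudo_count

    def fit(self, observations, y=None):
        """*observations*: iterable of (dssp_state, psipred_state,
        confidence 0-9) triples."""
        counts = np.zeros((8, 3, 10)) + self.pseudo_count
        for d, p, c in observations:
            counts[DSSP_STATES.index(d), PSIPRED_STATES.index(p), int(c)] += 1
        total = counts.sum()
        p_joint = counts / total
        p_d = p_joint.sum(axis=(1, 2))
        p_pc = p_joint.sum(axis=0)
        denom = p_d[:, None, None] * p_pc[None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            table = np.log(p_joint / denom)
        self.table_ = np.where(denom > 0, table, 0.0)
        return self

    def score(self, dssp_state: str, psipred_state: str,
              confidence: int) -> float:
        return float(self.table_[DSSP_STATES.index(dssp_state),
                                 PSIPRED_STATES.index(psipred_state),
                                 int(confidence)])

    def to_dict(self) -> dict:
        return {"pseudo_count": self.pseudo_count,
                "table": self.table_.tolist(), "format_version": 1}

    @classmethod
    def from_dict(cls, d) -> "SSAgreementTable":
        obj = cls(pseudo_count=d["pseudo_count"])
        obj.table_ = np.asarray(d["table"])
        return obj


def ss_agreement(table: SSAgreementTable, dssp_states, psipred) -> np.ndarray:
    """Per-residue S(d, p, c); *psipred* is a list of (state, confidence)."""
    return np.array([
        table.score(d, p, c) for d, (p, c) in zip(dssp_states, psipred)
    ])


def acc_agreement(asa: np.ndarray, sequence: str, accpro_states) -> np.ndarray:
    """1 where the burial class of the model matches the two-state
    prediction, 0 otherwise; NaN for residues of unknown type.

    A residue is buried when its relative accessibility is strictly below
    25% of the residue-type maximum.
    """
    rel = relative_accessibility(asa, sequence)
    out = np.full(len(sequence), np.nan)
    for i, (r, pred) in enumerate(zip(rel, accpro_states)):
        if np.isnan(r):
            continue
        observed = "b" if r < _BURIAL_CUT else "e"
        out[i] = 1.0 if observed == pred else 0.0
    return out


# ---------------------------------------------------------------------------
# Clash score, residue count, smoothing
# ---------------------------------------------------------------------------

def clash_score(s: Structure) -> np.ndarray:
    """SCWRL3-style hard-sphere overlap penalty, summed per residue and
    sign-flipped (0 = clash-free, negative = clashing).

    Pairs between sequence-adjacent residues are excluded, covering the
    covalent peptide bond and its 1-3 neighbours.
    """
    coords, res_idx, names = s.atom_table()
    n = len(s)
    out = np.zeros(n)
    if len(coords) == 0:
        return out
    radii = np.array([CLASH_RADII.get(element_of(nm), 1.6) for nm in names])
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    iu, ju = np.triu_indices(len(coords), k=1)
    mask = np.abs(res_idx[iu] - res_idx[ju]) >= 2
    iu, ju = iu[mask], ju[mask]
    rij = radii[iu] + radii[ju]
    dij = d[iu, ju]
    with np.errstate(invalid="ignore"):
        pen = np.clip(
            CLASH_MAX_PENALTY * (rij - dij) / ((1 - CLASH_LINEAR_ONSET) * rij),
            0.0, CLASH_MAX_PENALTY,
        )
    np.add.at(out, res_idx[iu], pen)
    np.add.at(out, res_idx[ju], pen)
    return -out


def residue_count(s: Structure, radius: float = 15.0) -> np.ndarray:
    """Number of other residues with Calpha within *radius*; NaN where the
    residue itself has no Calpha."""
    ca = s.ca_array()
    valid = ~np.isnan(ca[:, 0])
    out = np.full(len(s), np.nan)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out
    d = np.linalg.norm(ca[idx, None] - ca[None, idx], axis=-1)
    counts = ((d < radius).sum(axis=1) - 1).astype(float)
    out[idx] = counts
    return out


def spherical_smooth(values, s: Structure, sigma: float = 5.0) -> np.ndarray:
    """Gaussian-weighted spatial smoothing over Calpha distances.

    smoothed_i = sum_j w_ij v_j / sum_j w_ij with w_ij = exp(-d_ij^2 /
    (2 sigma^2)), summing over valid residues j including j = i (weight 1).
    Invalid (NaN) inputs are excluded from the sums; a residue whose own
    value is invalid and that has no valid neighbour stays invalid.
    """
    v = np.asarray(values, dtype=float)
    ca = s.ca_array()
    valid = ~np.isnan(v)
    has_ca = ~np.isnan(ca[:, 0])
    out = np.full(len(v), np.nan)
    vi = valid & has_ca
    if not vi.any():
        # no spatial information: valid residues keep their value
        out[valid] = v[valid]
        return out
    src = np.flatnonzero(vi)
    d2 = ((ca[:, None, :] - ca[None, src, :]) ** 2).sum(axis=-1)
    w = np.exp(-d2 / (2.0 * sigma * sigma))
    w[~has_ca, :] = 0.0
    num = w @ v[src]
    den = w.sum(axis=1)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    # residues without Calpha cannot borrow neighbours but keep their value
    noca = valid & ~has_ca
    out[noca] = v[noca]
    return out


# ---------------------------------------------------------------------------
# Predictor-file readers
# ---------------------------------------------------------------------------

def read_psipred_ss2(path) -> list:
    """PSIPRED vertical (.ss2) reader -> list of (state, confidence 0-9).

    Columns: index, residue, state, p_coil, p_helix, p_strand.  The
    confidence is derived from the winning probability.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6 or not parts[0].isdigit():
                continue
            state = parts[2]
            probs = [float(x) for x in parts[3:6]]
            conf = min(9, int(round(max(probs) * 10)) )
            if state not in PSIPRED_STATES:
                state = "C"
            out.append((state, conf))
    return out


def read_accpro(path) -> str:
    """ACCpro two-state reader -> string of 'b' (buried) / 'e' (exposed).

    Accepts FASTA-like files where the prediction line uses 'e' for exposed
    and '-' or 'b' for buried.
    """
    states = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            for ch in line:
                states.append("e" if ch in "eE" else "b")
    return "".join(states)
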
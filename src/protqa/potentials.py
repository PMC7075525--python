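"""Statistical potentials of mean force.

Six knowledge-based terms trained from a corpus of experimentally plausible
structures by inverse-Boltzmann statistics:

* ``all_atom``   — pairwise distances between all chemically distinguishable
                   heavy atoms (167-type alphabet),
* ``cb_interaction`` — pairwise Cbeta–Cbeta distances (Cbeta inferred from
                   the backbone for glycine),
* ``reduced``    — pairwise geometry of a reduced residue representation
                   (Calpha position + backbone direction vector), binned on
                   distance and inter-direction angle,
* ``packing``    — per-atom count of surrounding heavy atoms,
* ``cb_packing`` — same concept on Cbeta representatives,
* ``torsion``    — central phi/psi of residue triplets, keyed by a grouped
                   identity triplet.

For every term the pseudo-energy of a bin given an interaction type is

    e(bin | type) = -log[ (f_obs(bin|type) + sigma * f_ref(bin))
                          / ((1 + sigma) * f_ref(bin)) ]

with ``f_obs`` the type-conditional normalized counts, ``f_ref`` the
type-pooled reference distribution and ``sigma`` a pseudo-count weight
(Sippl-style sparse-data handling).  Types never observed in the corpus
fall back to the reference (zero energy everywhere).

Per-residue scores are sign-flipped on output so that, like every other
feature in the package, higher means better.
"""

from __future__ import annotations

import json
import logging

import numpy as np
from sklearn.base import BaseEstimator

from .constants import ATOM_TYPES, N_ATOM_TYPES, AMINO_ACIDS, N_TORSION_GROUPS, torsion_group
from .geometry import dihedral
from .structure import Structure, infer_cb

logger = logging.getLogger(__name__)

TERMS = ("all_atom", "cb_interaction", "reduced", "packing", "cb_packing",
         "torsion")
INTERACTION_TERMS = ("all_atom", "cb_interaction", "reduced")
PACKING_TERMS = ("packing", "cb_packing")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)
_PEPTIDE_BOND_MAX = 2.5  # A, C(i)-N(i+1) distance for chain continuity


def _pair_type(t1: int, t2: int, n: int) -> int:
    """Canonical index of an unordered type pair."""
    a, b = (t1, t2) if t1 <= t2 else (t2, t1)
    return a * n + b


class StatisticalPotential(BaseEstimator):
    """One trainable statistical-potential term (scikit-learn style).

    Parameters
    ----------
    term:
        One of ``all_atom``, ``cb_interaction``, ``reduced``, ``packing``,
        ``cb_packing``, ``torsion``.
    sigma:
        Pseudo-count weight of the reference distribution.
    seq_sep:
        Minimum |i - j| for interaction terms (focus on long-range
        contacts; helical i,i+4 contacts are excluded at the default).
    """

    def __init__(self, term: str = "all_atom", sigma: float = 0.02,
                 seq_sep: int = 5, interaction_bin: float = 0.5,
                 interaction_max: float = 20.0, reduced_max: float = 15.0,
                 reduced_dist_bin: float = 1.0, reduced_angle_bin: float = 30.0,
                 packing_radius: float = 10.0, packing_max_count: int = 32,
                 torsion_bin: float = 30.0):
        self.term = term
        self.sigma = sigma
        self.seq_sep = seq_sep
        self.interaction_bin = interaction_bin
        self.interaction_max = interaction_max
        self.reduced_max = reduced_max
        self.reduced_dist_bin = reduced_dist_bin
        self.reduced_angle_bin = reduced_angle_bin
        self.packing_radius = packing_radius
        self.packing_max_count = packing_max_count
        self.torsion_bin = torsion_bin

    # -- table geometry ----------------------------------------------------

    def _shape(self):
        if self.term == "all_atom":
            nbin = int(round(self.interaction_max / self.interaction_bin))
            return N_ATOM_TYPES * N_ATOM_TYPES, nbin
        if self.term == "cb_interaction":
            nbin = int(round(self.interaction_max / self.interaction_bin))
            return _N_AA * _N_AA, nbin
        if self.term == "reduced":
            nd = int(round(self.reduced_max / self.reduced_dist_bin))
            na = int(round(180.0 / self.reduced_angle_bin))
            return _N_AA * _N_AA, nd * na
        if self.term == "packing":
            return N_ATOM_TYPES, self.packing_max_count + 1
        if self.term == "cb_packing":
            return _N_AA, self.packing_max_count + 1
        if self.term == "torsion":
            nb = int(round(360.0 / self.torsion_bin))
            return N_TORSION_GROUPS ** 3, nb * nb
        raise ValueError(f"unknown term {self.term!r}")

    # -- event extraction --------------------------------------------------
    # Every observation is a (type index, bin index) event plus, for
    # scoring, the residue indices it contributes to.

    def _interaction_events(self, s: Structure):
        coords, res, types, dirs = [], [], [], []
        if self.term == "all_atom":
            n_types = N_ATOM_TYPES
            for r in s:
                for name, xyz in r.atoms.items():
                    t = ATOM_TYPES.get((r.aa, name))
                    if t is not None:
                        coords.append(xyz)
                        res.append(r.index)
                        types.append(t)
        elif self.term == "cb_interaction":
            n_types = _N_AA
            for r in s:
                cb = infer_cb(r)
                if cb is not None and r.aa in _AA_INDEX:
                    coords.append(cb)
                    res.append(r.index)
                    types.append(_AA_INDEX[r.aa])
        else:  # reduced representation: Calpha + backbone direction
            n_types = _N_AA
            for r in s:
                if r.has_backbone and r.aa in _AA_INDEX:
                    ca = r.atoms["CA"]
                    u1 = ca - r.atoms["N"]
                    u2 = ca - r.atoms["C"]
                    u1 = u1 / np.linalg.norm(u1)
                    u2 = u2 / np.linalg.norm(u2)
                    u = u1 + u2
                    u = u / np.linalg.norm(u)
                    coords.append(ca)
                    res.append(r.index)
                    types.append(_AA_INDEX[r.aa])
                    dirs.append(u)
        if len(coords) < 2:
            return (np.zeros(0, dtype=int),) * 3
        coords = np.asarray(coords)
        res = np.asarray(res)
        types = np.asarray(types)
        d_max = (self.reduced_max if self.term == "reduced"
                 else self.interaction_max)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        iu, ju = np.triu_indices(len(coords), k=1)
        mask = (np.abs(res[iu] - res[ju]) >= self.seq_sep) & (d[iu, ju] < d_max)
        iu, ju = iu[mask], ju[mask]
        if self.term == "reduced":
            dirs = np.asarray(dirs)
            cosang = np.clip((dirs[iu] * dirs[ju]).sum(axis=1), -1.0, 1.0)
            ang = np.degrees(np.arccos(cosang))
            na = int(round(180.0 / self.reduced_angle_bin))
            abin = np.minimum((ang / self.reduced_angle_bin).astype(int),
                              na - 1)
            dbin = (d[iu, ju] / self.reduced_dist_bin).astype(int)
            bins = dbin * na + abin
        else:
            bins = (d[iu, ju] / self.interaction_bin).astype(int)
        lo = np.minimum(types[iu], types[ju])
        hi = np.maximum(types[iu], types[ju])
        pair_types = lo * n_types + hi
        return pair_types, bins, np.stack([res[iu], res[ju]], axis=1)

    def _packing_events(self, s: Structure):
        if self.term == "packing":
            coords, res, types = [], [], []
            for r in s:
                for name, xyz in r.atoms.items():
                    t = ATOM_TYPES.get((r.aa, name))
                    if t is not None:
                        coords.append(xyz)
                        res.append(r.index)
                        types.append(t)
        else:
            coords, res, types = [], [], []
            for r in s:
                cb = infer_cb(r)
                if cb is not None and r.aa in _AA_INDEX:
                    coords.append(cb)
                    res.append(r.index)
                    types.append(_AA_INDEX[r.aa])
        if not coords:
            return (np.zeros(0, dtype=int),) * 3
        coords = np.asarray(coords)
        res = np.asarray(res)
        types = np.asarray(types, dtype=int)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        other = res[:, None] != res[None, :]
        counts = ((d < self.packing_radius) & other).sum(axis=1)
        counts = np.minimum(counts, self.packing_max_count)
        return types, counts, res

    def _torsion_events(self, s: Structure):
        seq = "".join(r.aa for r in s)
        nb = int(round(360.0 / self.torsion_bin))
        types, bins, res = [], [], []
        for i in range(1, len(s) - 1):
            prev_r, r, next_r = s[i - 1], s[i], s[i + 1]
            if not (prev_r.has_backbone and r.has_backbone
                    and next_r.has_backbone):
                continue
            # require intact peptide bonds (guards against chain breaks)
            if (np.linalg.norm(prev_r.atoms["C"] - r.atoms["N"])
                    > _PEPTIDE_BOND_MAX):
                continue
            if (np.linalg.norm(r.atoms["C"] - next_r.atoms["N"])
                    > _PEPTIDE_BOND_MAX):
                continue
            phi = dihedral(prev_r.atoms["C"], r.atoms["N"], r.atoms["CA"],
                           r.atoms["C"])
            psi = dihedral(r.atoms["N"], r.atoms["CA"], r.atoms["C"],
                           next_r.atoms["N"])
            pb = min(int((phi + 180.0) / self.torsion_bin), nb - 1)
            sb = min(int((psi + 180.0) / self.torsion_bin), nb - 1)
            key = (torsion_group(seq, i - 1) * N_TORSION_GROUPS ** 2
                   + torsion_group(seq, i) * N_TORSION_GROUPS
                   + torsion_group(seq, i + 1))
            types.append(key)
            bins.append(pb * nb + sb)
            res.append(r.index)
        return (np.asarray(types, dtype=int), np.asarray(bins, dtype=int),
                np.asarray(res, dtype=int))

    def _events(self, s: Structure):
        if self.term in INTERACTION_TERMS:
            return self._interaction_events(s)
        if self.term in PACKING_TERMS:
            return self._packing_events(s)
        return self._torsion_events(s)

    # -- training ----------------------------------------------------------

    def fit(self, corpus, y=None):
        """Count observations over *corpus* (list of Structure) and convert
        them to pseudo-energies.  Counting is order-independent."""
        if not corpus:
            raise ValueError("empty training corpus")
        n_types, n_bins = self._shape()
        counts = np.zeros((n_types, n_bins), dtype=np.int64)
        for s in corpus:
            t, b, _ = self._events(s)
            if len(t):
                np.add.at(counts, (t, b), 1)
        self.counts_ = counts
        self.energies_ = self._energies_from_counts(counts)
        self.n_structures_ = len(corpus)
        return self

    def _energies_from_counts(self, counts):
        total = counts.sum()
        if total == 0:
            logger.warning("%s: corpus produced no observations", self.term)
            return np.zeros(counts.shape)
        f_ref = counts.sum(axis=0) / total
        row = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_obs = np.where(row > 0, counts / np.maximum(row, 1), 0.0)
            ratio = (f_obs + self.sigma * f_ref[None, :]) / (
                (1.0 + self.sigma) * f_ref[None, :]
            )
            e = -np.log(ratio)
        e[:, f_ref == 0] = 0.0
        e[row[:, 0] == 0, :] = 0.0  # unseen types fall back to reference
        return np.nan_to_num(e)

    # -- scoring -----------------------------------------------------------

    def score_residues(self, model: Structure) -> np.ndarray:
        """Per-residue sign-flipped mean pseudo-energy; NaN where a residue
        has no contributing observations."""
        if not hasattr(self, "energies_"):
            raise RuntimeError("potential not trained")
        n = len(model)
        acc = np.zeros(n)
        cnt = np.zeros(n)
        t, b, res = self._events(model)
        if len(t):
            e = self.energies_[t, b]
            if self.term in INTERACTION_TERMS:
                np.add.at(acc, res[:, 0], e)
                np.add.at(acc, res[:, 1], e)
                np.add.at(cnt, res[:, 0], 1)
                np.add.at(cnt, res[:, 1], 1)
            else:
                np.add.at(acc, res, e)
                np.add.at(cnt, res, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(cnt > 0, -acc / np.maximum(cnt, 1), np.nan)
        return out

    # -- serialization -----------------------------------------------------

    def to_npz(self, path) -> None:
        meta = json.dumps(self.get_params() | {
            "n_structures": int(getattr(self, "n_structures_", 0)),
            "format_version": 1,
        })
        np.savez_compressed(path, energies=self.energies_,
                            counts=self.counts_, meta=np.str_(meta))

    @classmethod
    def from_npz(cls, path) -> "StatisticalPotential":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        n_structures = meta.pop("n_structures", 0)
        meta.pop("format_version", None)
        obj = cls(**meta)
        obj.energies_ = data["energies"]
        obj.counts_ = data["counts"]
        obj.n_structures_ = n_structures
        return obj


def train_all_terms(corpus, sigma: float = 0.02, **kwargs) -> dict:
    """Train all six terms on one corpus; returns term -> estimator."""
    return {
        term: StatisticalPotential(term=term, sigma=sigma, **kwargs).fit(corpus)
        for term in TERMS
    }


def score_all_terms(potentials: dict, model: Structure) -> dict:
    """term -> per-residue score array for a model."""
    return {term: p.score_residues(model) for term, p in potentials.items()}
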
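"""Synthetic structure and input generation.

Every input the scoring pipeline consumes can be generated here without
external data: idealized native structures (full backbone + Cbeta built
from ideal phi/psi segments), noise-perturbed "models" of controllable
quality, perturbed/truncated/mutated "templates" with a consistent A3M
alignment, and mock secondary-structure/accessibility predictor files.

Geometry is idealized (fixed bond lengths and angles; helix, strand and
coil segments differ only in their torsions) and natives are rejection-
resampled until they are free of hard-sphere clashes, so the clash term is
zero on every native by construction.  Identical seeds give bit-identical
output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .constants import AMINO_ACIDS, CLASH_RADII, element_of
from .geometry import place_atom
from .local_features import (assign_secondary_structure, relative_accessibility,
                             solvent_accessibility)
from .structure import Residue, Structure, extract_sequence, write_pdb

# ideal backbone internal coordinates (A / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0

_TORSIONS = {
    "H": (-57.0, -47.0),
    "E": (-139.0, 135.0),
}
_COIL_BASINS = [(-70.0, 140.0), (-90.0, 0.0), (-120.0, 120.0),
                (-60.0, -40.0), (60.0, 40.0)]

_CB_BOND, _CB_ANGLE, _CB_DIHEDRAL = 1.53, 110.4, 122.55


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic modelling target."""
    seed: int = 7
    length: int = 45
    layout: str | None = None            # per-residue H/E/C, random if None
    noise_amplitudes: tuple = tuple(np.linspace(0.0, 3.0, 8))
    n_templates: int = 4
    template_noise: tuple = (0.3, 1.5)   # A, uniform range
    template_coverage: tuple = (0.7, 1.0)
    template_identity: tuple = (0.35, 0.9)
    predictor_error_rate: float = 0.15


def random_layout(length: int, rng: np.random.Generator) -> str:
    """Random secondary-structure layout: helix/strand segments separated
    by coil linkers (structured elements never abut directly)."""
    out = list("C" * int(rng.integers(2, 5)))
    while len(out) < length:
        state = "H" if rng.random() < 0.6 else "E"
        seg = int(rng.integers(8, 15) if state == "H"
                  else rng.integers(5, 9))
        out.extend(state * seg)
        out.extend("C" * int(rng.integers(3, 7)))
    return "".join(out[:length])


def _torsions_for_layout(layout: str, rng: np.random.Generator):
    phi, psi = [], []
    for state in layout:
        if state in _TORSIONS:
            p0, s0 = _TORSIONS[state]
            jitter = 3.0
        else:
            p0, s0 = _COIL_BASINS[rng.integers(len(_COIL_BASINS))]
            jitter = 15.0
        phi.append(p0 + rng.uniform(-jitter, jitter))
        psi.append(s0 + rng.uniform(-jitter, jitter))
    return phi, psi


def build_backbone(sequence: str, phi, psi) -> Structure:
    """Chain from ideal internal coordinates; atoms N, CA, C, O (+CB)."""
    n_res = len(sequence)
    coords = []  # (N, CA, C) per residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords.append([n0, ca0, c0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N,
                         psi[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi[i])
        coords.append([n_i, ca_i, c_i])
    residues = []
    for i, aa in enumerate(sequence):
        n_i, ca_i, c_i = coords[i]
        atoms = {"N": n_i, "CA": ca_i, "C": c_i}
        if i + 1 < n_res:
            atoms["O"] = place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O,
                                    psi[i] + 180.0)
        else:
            atoms["O"] = place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, 0.0)
        if aa != "G":
            atoms["CB"] = place_atom(c_i, n_i, ca_i, _CB_BOND, _CB_ANGLE,
                                     _CB_DIHEDRAL)
        residues.append(Residue(index=i, number=i + 1, icode="", aa=aa,
                                atoms=atoms))
    return Structure("synthetic", residues)


def _has_clashes(s: Structure, margin: float = 0.05) -> bool:
    coords, res_idx, names = s.atom_table()
    radii = np.array([CLASH_RADII.get(element_of(nm), 1.6) for nm in names])
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    iu, ju = np.triu_indices(len(coords), k=1)
    mask = np.abs(res_idx[iu] - res_idx[ju]) >= 2
    rij = radii[iu[mask]] + radii[ju[mask]]
    return bool((d[iu[mask], ju[mask]] < rij + margin).any())


def make_native(scenario: SyntheticScenario,
                max_retries: int = 300) -> Structure:
    """Clash-free idealized native for a scenario (deterministic)."""
    rng = np.random.default_rng(scenario.seed)
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=scenario.length))
    for _ in range(max_retries):
        layout = scenario.layout or random_layout(scenario.length, rng)
        phi, psi = _torsions_for_layout(layout, rng)
        s = build_backbone(sequence, phi, psi)
        if not _has_clashes(s):
            s.id = f"native_{scenario.seed}"
            return s
    raise RuntimeError(
        f"could not place a clash-free chain for seed {scenario.seed}")


def perturb(s: Structure, amplitude: float, rng: np.random.Generator,
            struct_id: str | None = None) -> Structure:
    """Copy with i.i.d. zero-mean Gaussian displacement of every atom."""
    residues = []
    for r in s:
        atoms = {
            name: xyz + rng.normal(0.0, amplitude, 3) if amplitude > 0
            else xyz.copy()
            for name, xyz in r.atoms.items()
        }
        residues.append(Residue(r.index, r.number, r.icode, r.aa, atoms))
    return Structure(struct_id or s.id, residues)


def delete_segment(s: Structure, start: int, stop: int) -> Structure:
    """Copy without residues [start, stop); indices re-packed, author
    numbering kept so models remain mappable to the native."""
    residues = []
    for r in s:
        if start <= r.index < stop:
            continue
        residues.append(Residue(len(residues), r.number, r.icode, r.aa,
                                {k: v.copy() for k, v in r.atoms.items()}))
    return Structure(s.id, residues)


def mapping_by_number(model: Structure, native: Structure) -> dict:
    """model residue index -> native residue index via author numbering."""
    by_number = {r.number: r.index for r in native}
    return {r.index: by_number[r.number] for r in model
            if r.number in by_number}


def make_models(native: Structure, noise_amplitudes, seed: int,
                deletions=None) -> list:
    """Perturbed copies of the native, one per amplitude.  *deletions*
    optionally maps model position -> (start, stop) segment to remove."""
    out = []
    for m_idx, a in enumerate(noise_amplitudes):
        rng = np.random.default_rng((seed * 10007 + m_idx) % (2 ** 31))
        m = perturb(native, float(a), rng,
                    struct_id=f"{native.id}_m{m_idx}")
        if deletions and m_idx in deletions:
            start, stop = deletions[m_idx]
            m = delete_segment(m, start, stop)
        out.append(m)
    return out


def make_templates_and_alignments(native: Structure,
                                  scenario: SyntheticScenario,
                                  out_dir) -> tuple[str, str]:
    """Write template PDBs plus a consistent A3M; returns (a3m_path,
    template_dir).  Templates are noise-perturbed, truncated and
    point-mutated copies of the native."""
    rng = np.random.default_rng((scenario.seed * 7919 + 1) % (2 ** 31))
    seq = extract_sequence(native)
    length = len(seq)
    os.makedirs(out_dir, exist_ok=True)
    tpl_dir = os.path.join(str(out_dir), "templates")
    os.makedirs(tpl_dir, exist_ok=True)
    lines = [f">target_{scenario.seed}", seq]
    for t_idx in range(scenario.n_templates):
        noise = rng.uniform(*scenario.template_noise)
        coverage = rng.uniform(*scenario.template_coverage)
        identity = rng.uniform(*scenario.template_identity)
        span = max(3, int(round(coverage * length)))
        start = int(rng.integers(0, length - span + 1))
        stop = start + span
        n_mut = int(round((1.0 - identity) * span))
        mut_pos = set(rng.choice(np.arange(start, stop), size=n_mut,
                                 replace=False)) if n_mut else set()
        tpl_seq = []
        residues = []
        for i in range(start, stop):
            aa = seq[i]
            if i in mut_pos:
                choices = [x for x in AMINO_ACIDS if x != aa]
                aa = choices[int(rng.integers(len(choices)))]
            tpl_seq.append(aa)
            src = native[i]
            atoms = {}
            for name, xyz in src.atoms.items():
                if name == "CB" and aa == "G":
                    continue
                atoms[name] = xyz + rng.normal(0.0, noise, 3)
            if aa != "G" and "CB" not in atoms and src.has_backbone:
                atoms["CB"] = place_atom(
                    src.atoms["C"], src.atoms["N"], src.atoms["CA"],
                    _CB_BOND, _CB_ANGLE, _CB_DIHEDRAL,
                ) + rng.normal(0.0, noise, 3)
            residues.append(Residue(len(residues), len(residues) + 1, "",
                                    aa, atoms))
        tpl_id = f"tpl_{scenario.seed}_{t_idx}"
        write_pdb(Structure(tpl_id, residues), os.path.join(tpl_dir,
                                                            f"{tpl_id}.pdb"))
        aligned = "-" * start + "".join(tpl_seq) + "-" * (length - stop)
        lines += [f">{tpl_id}", aligned]
    a3m_path = os.path.join(str(out_dir), f"target_{scenario.seed}.a3m")
    with open(a3m_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return a3m_path, tpl_dir


def collapse_to_three_states(state: str) -> str:
    if state in "GHI":
        return "H"
    if state in "EB":
        return "E"
    return "C"


def make_predictor_files(native: Structure, error_rate: float, seed: int,
                         ss2_path, acc_path) -> None:
    """Mock PSIPRED (.ss2) and ACCpro-style (.acc) files derived from the
    native's own secondary structure and burial, corrupted at *error_rate*
    with confidences anticorrelated with the corruption."""
    rng = np.random.default_rng(seed % (2 ** 31))
    seq = extract_sequence(native)
    states = [collapse_to_three_states(s)
              for s in assign_secondary_structure(native)]
    rel = relative_accessibility(solvent_accessibility(native), seq)
    with open(ss2_path, "w") as fh:
        fh.write("# PSF format result\n\n")
        for i, (aa, state) in enumerate(zip(seq, states)):
            corrupted = rng.random() < error_rate
            if corrupted:
                state = {"H": "E", "E": "C", "C": "H"}[state]
                p_win = rng.uniform(0.4, 0.6)
            else:
                p_win = rng.uniform(0.8, 0.98)
            rest = (1.0 - p_win) / 2.0
            probs = {"C": rest, "H": rest, "E": rest}
            probs[state] = p_win
            fh.write(f"{i + 1:4d} {aa} {state}  {probs['C']:.3f} "
                     f"{probs['H']:.3f} {probs['E']:.3f}\n")
    with open(acc_path, "w") as fh:
        fh.write(f">{native.id}\n")
        chars = []
        for i in range(len(seq)):
            buried = (not np.isnan(rel[i])) and rel[i] < 0.25
            if rng.random() < error_rate:
                buried = not buried
            chars.append("-" if buried else "e")
        fh.write("".join(chars) + "\n")


def make_training_corpus(n_structures: int, seed: int,
                         length_range=(25, 40)) -> list:
    """Clash-free natives for statistical-potential training."""
    corpus = []
    rng = np.random.default_rng(seed)
    for k in range(n_structures):
        length = int(rng.integers(*length_range))
        scen = SyntheticScenario(seed=int(rng.integers(2 ** 31)),
                                 length=length)
        corpus.append(make_native(scen))
    return corpus


@dataclass
class TargetBundle:
    """Everything generated for one synthetic modelling target."""
    scenario: SyntheticScenario
    native: Structure
    models: list
    a3m_path: str
    template_dir: str
    ss2_path: str
    acc_path: str


def make_target_bundle(scenario: SyntheticScenario, out_dir) -> TargetBundle:
    native = make_native(scenario)
    native.id = f"target_{scenario.seed}"
    models = make_models(native, scenario.noise_amplitudes, scenario.seed)
    a3m_path, tpl_dir = make_templates_and_alignments(native, scenario,
                                                      out_dir)
    ss2_path = os.path.join(str(out_dir), f"{native.id}.ss2")
    acc_path = os.path.join(str(out_dir), f"{native.id}.acc")
    make_predictor_files(native, scenario.predictor_error_rate,
                         scenario.seed * 13 + 5, ss2_path, acc_path)
    return TargetBundle(scenario, native, models, a3m_path, tpl_dir,
                        ss2_path, acc_path)
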
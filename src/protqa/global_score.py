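"""Global model score, coverage normalization and expected-error model.

The global score is the arithmetic mean of valid per-residue predictions.
Because the score judges the model "as is" while lDDT penalises missing
residues, a coverage pre-factor (fraction of target residues present in
the model) yields the normalized variant used for comparisons against
full-length reference scores.  The expected error at a given model length
is the RMS of absolute global-prediction errors of reference models with
length within +-40 residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import Structure, extract_sequence

logger = logging.getLogger(__name__)

LENGTH_WINDOW = 40
_MIN_WINDOW_POINTS = 30


def global_from_local(per_residue) -> float:
    v = np.asarray(per_residue, dtype=float)
    valid = np.isfinite(v)
    if not valid.any():
        raise ValueError("no valid per-residue predictions")
    return float(v[valid].mean())


def model_coverage(model: Structure, target_sequence: str) -> float:
    """Fraction of target residues present in the model (sequence match
    of the model's residues against the target by greedy in-order
    alignment of identical letters)."""
    if not target_sequence:
        raise ValueError("empty target sequence")
    model_seq = extract_sequence(model)
    t = 0
    matched = 0
    for aa in model_seq:
        while t < len(target_sequence) and target_sequence[t] != aa:
            t += 1
        if t == len(target_sequence):
            break
        matched += 1
        t += 1
    return matched / len(target_sequence)


def coverage_normalize(global_score: float, model: Structure,
                       target_sequence: str) -> float:
    return model_coverage(model, target_sequence) * global_score


@dataclass
class ErrorModel:
    """Reference (model_length, |predicted - actual global lDDT|) pairs."""
    lengths: np.ndarray
    abs_errors: np.ndarray
    window: int = LENGTH_WINDOW

    @classmethod
    def from_predictions(cls, lengths, predicted, actual,
                         window: int = LENGTH_WINDOW) -> "ErrorModel":
        lengths = np.asarray(lengths, dtype=float)
        err = np.abs(np.asarray(predicted, float) - np.asarray(actual, float))
        return cls(lengths=lengths, abs_errors=err, window=window)

    def expected_error(self, model_length: int) -> float:
        """RMS absolute error over reference models of length within the
        window; if the window is empty it widens symmetrically until at
        least 30 points are covered."""
        if len(self.lengths) == 0:
            raise ValueError("empty error model")
        w = self.window
        mask = np.abs(self.lengths - model_length) <= w
        while mask.sum() == 0 or (mask.sum() < min(_MIN_WINDOW_POINTS,
                                                   len(self.lengths))
                                  and w < self.lengths.max() + self.window):
            w *= 2
            mask = np.abs(self.lengths - model_length) <= w
        if w != self.window:
            logger.info("expected_error: widened window to +-%d for "
                        "length %d", w, model_length)
        return float(np.sqrt(np.mean(self.abs_errors[mask] ** 2)))

    def to_dict(self) -> dict:
        return {"lengths": self.lengths.tolist(),
                "abs_errors": self.abs_errors.tolist(),
                "window": self.window, "format_version": 1}

    @classmethod
    def from_dict(cls, d) -> "ErrorModel":
        return cls(np.asarray(d["lengths"], float),
                   np.asarray(d["abs_errors"], float), d.get("window", 40))


@dataclass
class GlobalResult:
    global_score: float
    coverage: float
    normalized_score: float
    expected_error: float | None
    model_length: int


def summarize(per_residue, model: Structure, target_sequence: str,
              error_model: ErrorModel | None = None) -> GlobalResult:
    g = global_from_local(per_residue)
    cov = model_coverage(model, target_sequence)
    return GlobalResult(
        global_score=g,
        coverage=cov,
        normalized_score=cov * g,
        expected_error=(error_model.expected_error(len(model))
                        if error_model is not None else None),
        model_length=len(model),
    )
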
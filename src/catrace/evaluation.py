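"""Model-quality metrics for a predicted C-alpha model against a reference.

Predicted and reference C-alpha atoms are paired one-to-one by a greedy
distance-ascending matching under a 3 Angstrom cutoff. From the matching:

* recall        = matched / n_true
* precision     = matched / n_pred
* F1            = harmonic mean of precision and recall
* CA match      = matched / n_pred (precision-like, the fraction of the
                  model placed within the cutoff)
* sequence match = fraction of matched pairs with identical residue type
* CA quality    = CA match * n_pred / n_true, clamped to [0, 1] - a
                  completeness-aware score combining match precision with
                  model coverage.

The greedy pairing is deterministic (ties broken by lower index pair) and
is not guaranteed to maximize the number of pairs on adversarial inputs;
tests document where it differs from the optimal assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import BackboneModel


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]
    distances: np.ndarray
    n_pred: int
    n_true: int
    cutoff: float


@dataclass
class EvalReport:
    recall: float
    precision: float
    f1: float
    ca_match_score: float
    seq_match_score: float
    ca_quality_score: float
    rmsd_matched: float
    n_pred: int
    n_true: int
    n_matched: int

    def to_row(self, label: str = "") -> pd.DataFrame:
        """One CSV row with percentages formatted to one decimal."""
        return pd.DataFrame([{
            "model": label,
            "n_pred": self.n_pred,
            "n_true": self.n_true,
            "n_matched": self.n_matched,
            "recall_pct": round(100 * self.recall, 1),
            "precision_pct": round(100 * self.precision, 1),
            "f1_pct": round(100 * self.f1, 1),
            "ca_match_pct": round(100 * self.ca_match_score, 1),
            "seq_match_pct": round(100 * self.seq_match_score, 1),
            "ca_quality": round(self.ca_quality_score, 3),
            "rmsd_matched_A": round(self.rmsd_matched, 3),
        }])


def match_ca(predicted, reference, cutoff: float = 3.0) -> MatchResult:
    """Greedy one-to-one pairing of predicted to reference atoms.

    All cross pairs are sorted by distance (ties by predicted then
    reference index); a pair is accepted iff both atoms are still unused
    and the distance is within the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pred = np.asarray(predicted, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    n_pred, n_true = len(pred), len(ref)
    if n_pred == 0 or n_true == 0:
        return MatchResult([], np.zeros(0), n_pred, n_true, cutoff)
    d = cdist(pred, ref)
    ii, jj = np.nonzero(d <= cutoff)
    dd = d[ii, jj]
    order = np.lexsort((jj, ii, dd))
    used_p = np.zeros(n_pred, bool)
    used_r = np.zeros(n_true, bool)
    pairs, dists = [], []
    for t in order:
        i, j = ii[t], jj[t]
        if used_p[i] or used_r[j]:
            continue
        used_p[i] = used_r[j] = True
        pairs.append((int(i), int(j)))
        dists.append(dd[t])
    return MatchResult(pairs, np.asarray(dists), n_pred, n_true, cutoff)


def recall_precision_f1(match: MatchResult) -> tuple[float, float, float]:
    if match.n_true == 0:
        raise ValueError("recall undefined: reference has no residues")
    n = len(match.pairs)
    recall = n / match.n_true
    precision = n / match.n_pred if match.n_pred > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return recall, precision, f1


def ca_match_and_seq_scores(
    match: MatchResult, predicted_residues, reference_residues
) -> tuple[float, float]:
    """(fraction of the model matched, identity fraction among matches)."""
    if match.n_pred == 0:
        return 0.0, 0.0
    n = len(match.pairs)
    ca_match = n / match.n_pred
    if n == 0:
        return ca_match, 0.0
    same = sum(
        1 for i, j in match.pairs
        if predicted_residues[i] == reference_residues[j])
    return ca_match, same / n


def ca_quality_score(ca_match_score: float, n_pred: int, n_true: int) -> float:
    """match * coverage = ca_match_score * n_pred / n_true, clamped to [0, 1]."""
    if n_true <= 0:
        raise ValueError("n_true must be positive")
    return float(min(1.0, max(0.0, ca_match_score * n_pred / n_true)))


def evaluate_models(
    predicted: BackboneModel, reference: BackboneModel, cutoff: float = 3.0
) -> EvalReport:
    """Full metric suite for a model-reference pair."""
    if reference.n_residues == 0:
        raise ValueError("reference model is empty")
    match = match_ca(predicted.all_coords(), reference.all_coords(), cutoff)
    recall, precision, f1 = recall_precision_f1(match)
    ca_match, seq_match = ca_match_and_seq_scores(
        match, predicted.all_residues(), reference.all_residues())
    quality = ca_quality_score(ca_match, match.n_pred, match.n_true)
    rmsd = (float(np.sqrt(np.mean(match.distances ** 2)))
            if len(match.pairs) else float("nan"))
    return EvalReport(
        recall=recall, precision=precision, f1=f1,
        ca_match_score=ca_match, seq_match_score=seq_match,
        ca_quality_score=quality, rmsd_matched=rmsd,
        n_pred=match.n_pred, n_true=match.n_true, n_matched=len(match.pairs))
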
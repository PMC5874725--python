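"""Prediction scoring, chain classification, and decoy ranking.

A chain's prediction is summarized as (TP ratio, FP ratio): true predictions
over the number of targets, and false predictions over the number of
non-target residues.  On that unit square, *good* predictions are the upper
left quadrant (TP > 0.5, FP ≤ 0.5), *very bad* the lower right (FP > 0.5,
TP ≤ 0.5), *satisfying* anything else above the diagonal (TP > FP), and
*unsatisfying* the rest.  A chain's *standing* is its Euclidean distance from
the ideal point (FP, TP) = (0, 1); decoys are ranked by ascending standing.
When a GNM rank and a statistical-potential rank are combined, the combined
standing is the distance of the rank pair from (1, 1) — the decoy that both
methods would put first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

from .structure_io import DimerModel
from .interface_targets import TargetSet
from .scaffold_predictor import PredictionResult

__all__ = [
    "EvaluationRecord",
    "DecoyRanking",
    "AggregateSummary",
    "LengthRatio",
    "evaluate_chain",
    "evaluate_chain_lenient",
    "score_decoy_set",
    "DecoySetResult",
    "classify",
    "standing_of",
    "aggregate",
    "rank_decoys",
    "combined_standing",
    "sequence_length_ratio",
    "read_labels",
    "NEAR_NATIVE_FLAGS",
    "LABEL_FLAGS",
]

LABEL_FLAGS = ("native", "near_native", "far", "neutral")
#: Flags counted as near-native when scoring a ranking (the native structure
#: itself is the best possible "near-native" decoy).
NEAR_NATIVE_FLAGS = frozenset({"native", "near_native"})

QUADRANTS = ("good", "very_bad", "satisfying", "unsatisfying")


def classify(tp_ratio: float, fp_ratio: float) -> str:
    """Quadrant class of a (TP, FP) point; exhaustive and mutually exclusive."""
    if tp_ratio > 0.5 and fp_ratio <= 0.5:
        return "good"
    if fp_ratio > 0.5 and tp_ratio <= 0.5:
        return "very_bad"
    if tp_ratio > fp_ratio:
        return "satisfying"
    return "unsatisfying"


def standing_of(tp_ratio: float, fp_ratio: float) -> float:
    """Distance of (FP, TP) from the ideal point (0, 1); in [0, √2]."""
    return math.hypot(fp_ratio, 1.0 - tp_ratio)


@dataclass(frozen=True)
class EvaluationRecord:
    """TP/FP ratios, quadrant class and standing for one chain."""

    tp_ratio: float
    fp_ratio: float
    quadrant: str
    standing: float


def _make_record(tp: float, fp: float) -> EvaluationRecord:
    return EvaluationRecord(
        tp_ratio=tp, fp_ratio=fp, quadrant=classify(tp, fp), standing=standing_of(tp, fp)
    )


def evaluate_chain(pred: PredictionResult, targets: TargetSet) -> EvaluationRecord:
    """Score a prediction against the chain's target set.

    Requires 0 < n_targets < chain_length (both ratios well defined).
    """
    n = targets.chain_length
    n_t = targets.n_targets
    if n_t == 0:
        raise ValueError("chain has zero targets; TP ratio undefined")
    if n_t >= n:
        raise ValueError("all residues are targets; FP ratio undefined")
    t = targets.all_targets
    tp = len(pred.predicted & t) / n_t
    fp = len(pred.predicted - t) / (n - n_t)
    return _make_record(tp, fp)


def evaluate_chain_lenient(pred: PredictionResult, targets: TargetSet) -> EvaluationRecord:
    """Like :func:`evaluate_chain` but defined for degenerate target sets.

    With zero targets the TP ratio is 0 (nothing could be recovered); with an
    all-target chain the FP ratio is 0 (nothing could be falsely called).
    Used by the decoy pipeline, where fully separated decoys have no contacts.
    """
    n = targets.chain_length
    n_t = targets.n_targets
    t = targets.all_targets
    tp = len(pred.predicted & t) / n_t if n_t > 0 else 0.0
    fp = len(pred.predicted - t) / (n - n_t) if n_t < n else 0.0
    return _make_record(tp, fp)


class AggregateSummary(NamedTuple):
    """Set-level prediction quality, all values in percent."""

    tp_mean_pct: float
    fp_mean_pct: float
    good_pct: float
    very_bad_pct: float
    n: int


def aggregate(records: Sequence[EvaluationRecord]) -> AggregateSummary:
    """Arithmetic means of the ratios and quadrant class fractions, in percent."""
    if not records:
        raise ValueError("empty record list")
    n = len(records)
    return AggregateSummary(
        tp_mean_pct=100.0 * sum(r.tp_ratio for r in records) / n,
        fp_mean_pct=100.0 * sum(r.fp_ratio for r in records) / n,
        good_pct=100.0 * sum(r.quadrant == "good" for r in records) / n,
        very_bad_pct=100.0 * sum(r.quadrant == "very_bad" for r in records) / n,
        n=n,
    )


@dataclass
class DecoyRanking:
    """Decoys ordered by ascending standing, with near-native rank metrics.

    ``best_rank`` is the 1-based rank of the best near-native decoy;
    ``coverage`` counts near-native decoys among the top n, n being the total
    number of near-native decoys.
    """

    decoy_ids: list[str]
    standings: list[float]
    near_native: set[str]
    best_rank: int
    coverage: int

    def rank_of(self, decoy_id: str) -> int:
        return self.decoy_ids.index(decoy_id) + 1


def rank_decoys(
    evals: Mapping[str, Mapping[str, EvaluationRecord]],
    near_native: set[str],
    chain_select: str = "min",
) -> DecoyRanking:
    """Rank decoys by the selected chain's standing (ties broken by decoy id).

    ``evals`` maps decoy id to per-chain records keyed 'a'/'b';
    ``chain_select`` is 'a', 'b', or 'min' (per-decoy minimum standing).
    """
    if len(evals) < 2:
        raise ValueError("need at least 2 decoys to rank")
    if chain_select not in ("a", "b", "min"):
        raise ValueError(f"unknown chain_select {chain_select!r}")
    missing = near_native - set(evals)
    if missing:
        raise ValueError(f"near-native labels without decoys: {sorted(missing)}")
    if not near_native:
        raise ValueError("no near-native decoys labelled")

    def _standing(recs: Mapping[str, EvaluationRecord]) -> float:
        if chain_select == "min":
            return min(r.standing for r in recs.values())
        return recs[chain_select].standing

    scored = sorted((_standing(recs), did) for did, recs in evals.items())
    ids = [did for _, did in scored]
    standings = [s for s, _ in scored]
    n_nn = len(near_native)
    best_rank = next(i + 1 for i, did in enumerate(ids) if did in near_native)
    coverage = sum(1 for did in ids[:n_nn] if did in near_native)
    return DecoyRanking(
        decoy_ids=ids,
        standings=standings,
        near_native=set(near_native),
        best_rank=best_rank,
        coverage=coverage,
    )


def combined_standing(rank_gnm: int, rank_pot: int) -> float:
    """Distance of the (GNM rank, potential rank) pair from the ideal (1, 1)."""
    if rank_gnm < 1 or rank_pot < 1:
        raise ValueError("ranks are 1-based and must be >= 1")
    return math.hypot(rank_gnm - 1, rank_pot - 1)


class LengthRatio(NamedTuple):
    ratio: float
    high_ratio: bool


def sequence_length_ratio(dimer: DimerModel, min_length: int = 80) -> LengthRatio:
    """Longer/shorter chain-length ratio and the high-ratio heterodimer flag.

    ``high_ratio`` requires ratio > 2 and both chains longer than
    ``min_length`` residues (short chains saturate with contacts and are
    excluded from the high-ratio class).
    """
    la, lb = dimer.chain_a.length, dimer.chain_b.length
    if la == 0 or lb == 0:
        raise ValueError("empty chain")
    ratio = max(la, lb) / min(la, lb)
    return LengthRatio(ratio=ratio, high_ratio=ratio > 2 and min(la, lb) > min_length)


@dataclass
class DecoySetResult:
    """Full scoring of one decoy set.

    ``records`` maps decoy id -> {'a': record, 'b': record}; ``gnm_ranking``
    orders decoys by GNM standing.  When a potential is supplied,
    ``energies`` holds interface energies, ``pot_ranking`` the decoy ids by
    ascending energy, and ``combined`` the per-decoy combined standing of the
    two 1-based ranks.
    """

    records: dict[str, dict[str, EvaluationRecord]]
    gnm_ranking: DecoyRanking
    energies: Optional[dict[str, float]] = None
    pot_ranking: Optional[list[str]] = None
    combined: Optional[dict[str, float]] = None


def score_decoy_set(
    decoys: Sequence[tuple[str, DimerModel]],
    labels: Mapping[str, str],
    strategy: str = "spatial_3d",
    potential=None,
    chain_select: str = "min",
) -> DecoySetResult:
    """Run the adjustable protocol on every decoy and rank by standing.

    For each decoy, contact and first-layer targets are extracted from the
    decoy itself and both chains are predicted with the adjustable protocol;
    since rigid-body decoys leave each chain's internal geometry unchanged,
    what varies across decoys is the target set.  Degenerate target sets
    (fully separated decoys) are scored with the lenient evaluator.
    """
    from .interface_targets import extract_targets
    from .gnm_core import build_kirchhoff, eigendecompose
    from .scaffold_predictor import adjustable_predict
    from .statistical_potential import interface_energy

    unknown = set(d for d, _ in decoys) - set(labels)
    if unknown:
        raise ValueError(f"decoys without labels: {sorted(unknown)}")
    records: dict[str, dict[str, EvaluationRecord]] = {}
    cache: dict[tuple, PredictionResult] = {}
    for did, dimer in decoys:
        if did in records:
            raise ValueError(f"duplicate decoy id {did!r}")
        ts_a, ts_b = extract_targets(dimer)
        recs = {}
        for key, chain, ts in (("a", dimer.chain_a, ts_a), ("b", dimer.chain_b, ts_b)):
            # the contact network is rigid-transform invariant, so identical
            # Kirchhoff matrices (typical across rigid-body decoys) reuse the
            # eigendecomposition and prediction
            kirchhoff = build_kirchhoff(chain)
            sig = (key, kirchhoff.n, hash(kirchhoff.matrix.tobytes()))
            pred = cache.get(sig)
            if pred is None:
                spec = eigendecompose(kirchhoff)
                pred = adjustable_predict(chain, spec, strategy)
                cache[sig] = pred
            recs[key] = evaluate_chain_lenient(pred, ts)
        records[did] = recs
    near_native = {d for d, f in labels.items() if f in NEAR_NATIVE_FLAGS and d in records}
    gnm_ranking = rank_decoys(records, near_native, chain_select)
    energies = pot_ranking = combined = None
    if potential is not None:
        energies = {did: interface_energy(dimer, potential) for did, dimer in decoys}
        pot_ranking = [d for _, d in sorted((e, d) for d, e in energies.items())]
        pot_rank = {d: i + 1 for i, d in enumerate(pot_ranking)}
        combined = {
            d: combined_standing(gnm_ranking.rank_of(d), pot_rank[d]) for d in energies
        }
    return DecoySetResult(
        records=records,
        gnm_ranking=gnm_ranking,
        energies=energies,
        pot_ranking=pot_ranking,
        combined=combined,
    )


def read_labels(path) -> dict[str, str]:
    """Read a decoy label file: one ``decoy_id flag`` pair per line.

    Flags: native, near_native, far, neutral.  Lines starting with '#' are
    comments; duplicate ids are an error.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"malformed label line: {ln!r}")
            did, flag = parts
            if flag not in LABEL_FLAGS:
                raise ValueError(f"unknown label flag {flag!r} for {did}")
            if did in labels:
                raise ValueError(f"duplicate decoy id {did!r}")
            labels[did] = flag
    return labels
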
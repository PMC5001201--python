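"""Rank-stability (sensitivity) analysis.

Microarray intensities carry detector noise; to check that epicenter
lists are robust to it, every gene's expression level in both condition
profiles is independently scaled by a random factor of at most
``max_frac`` (default 5 %), the whole pipeline is re-run, and the
resulting rankings are aggregated over many repetitions — separately for
upward and downward perturbation.

Reproducibility: each multiplicative draw comes from a counter-based
stream keyed by (master seed, repetition, condition, gene), so results
are bit-identical for a given master seed, independent of gene ordering,
and repetitions may run in any order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .centrality import EpicenterRanking
from .core import BaseNetwork, ExpressionProfile
from .errors import ParameterError

__all__ = ["StabilityReport", "perturb_profile", "sensitivity_run"]


def _unit(master_seed: int, *key) -> float:
    """Deterministic uniform draw on (0, 1] keyed by (seed, *key)."""
    payload = repr((int(master_seed),) + key).encode()
    h = hashlib.blake2b(payload, digest_size=8).digest()
    return (int.from_bytes(h, "big") + 1) / 2.0 ** 64


def perturb_profile(expr: ExpressionProfile, direction: str, max_frac: float,
                    seed: int, rep: int = 0) -> ExpressionProfile:
    """Scale every intensity by ``1 + u`` (up) or ``1 - u`` (down),
    ``u ~ Uniform(0, max_frac]`` drawn independently per gene.

    ``max_frac = 0`` returns values identical to the input.  For
    direction ``down``, ``max_frac`` must stay below 1 to keep
    intensities positive.
    """
    if direction not in ("up", "down"):
        raise ParameterError(f"direction must be 'up' or 'down', got {direction!r}")
    if not (0 <= max_frac < 1):
        raise ParameterError(f"max_frac must lie in [0, 1), got {max_frac}")
    sign = 1.0 if direction == "up" else -1.0
    values = {
        g: v * (1.0 + sign * max_frac * _unit(seed, rep, expr.condition, g))
        for g, v in expr.values.items()
    }
    return ExpressionProfile(condition=expr.condition, values=values)


@dataclass
class StabilityReport:
    """Aggregated epicenter-list stability over repetitions."""

    direction: str
    max_frac: float
    reps: int
    seed: int
    top_ks: tuple[int, ...]
    #: per repetition: the specific-list ranking
    specific_rankings: list[EpicenterRanking] = field(repr=False)
    #: per repetition: the global-list ranking
    global_rankings: list[EpicenterRanking] = field(repr=False)
    #: k -> nodes present in the top-k of the specific list in EVERY repetition
    always_in_top_k: dict[int, set[str]] = field(default_factory=dict)
    #: node -> mean rank in the specific list over the reps where it appears
    mean_rank: dict[str, float] = field(default_factory=dict)
    #: (k, node) -> fraction of repetitions with the node in the top k
    top_k_frequency: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "direction": self.direction,
            "max_frac": self.max_frac,
            "reps": self.reps,
            "seed": self.seed,
            "top_ks": list(self.top_ks),
            "always_in_top_k": {str(k): sorted(v)
                                for k, v in self.always_in_top_k.items()},
            "mean_rank": {n: self.mean_rank[n] for n in sorted(self.mean_rank)},
            "top_k_frequency": {
                str(k): {n: f[n] for n in sorted(f)}
                for k, f in self.top_k_frequency.items()},
        }


def aggregate_rankings(rankings: list[EpicenterRanking],
                       top_ks: tuple[int, ...]) -> tuple[dict, dict, dict]:
    """Always-in-top-k sets, per-node mean rank and top-k frequencies."""
    reps = len(rankings)
    always: dict[int, set[str]] = {}
    for k in top_ks:
        per_rep = [{e.node for e in r.top(k)} for r in rankings]
        always[k] = set.intersection(*per_rep) if per_rep else set()
    ranks: dict[str, list[int]] = {}
    for r in rankings:
        for e in r.entries:
            ranks.setdefault(e.node, []).append(e.rank)
    mean_rank = {n: sum(v) / len(v) for n, v in ranks.items()}
    freq: dict[int, dict[str, float]] = {}
    for k in top_ks:
        counts: dict[str, int] = {}
        for r in rankings:
            for e in r.top(k):
                counts[e.node] = counts.get(e.node, 0) + 1
        freq[k] = {n: c / reps for n, c in counts.items()}
    return always, mean_rank, freq


def sensitivity_run(
    base: BaseNetwork,
    control: ExpressionProfile,
    perturbed: ExpressionProfile,
    *,
    reps: int = 100,
    direction: str = "up",
    max_frac: float = 0.05,
    top_ks: tuple[int, ...] = (10, 20),
    q: float = 0.1,
    top_k: int = 10,
    analyze: str = "perturbed",
    seed: int = 0,
) -> StabilityReport:
    """Re-run the full pipeline ``reps`` times on noise-perturbed profiles.

    Both condition profiles are perturbed independently per repetition
    (one draw per gene per condition).  ``analyze`` picks which CSHAN the
    rankings are computed on.  Aggregation is deterministic given the
    master ``seed`` regardless of execution order.
    """
    from .pipeline import run_stages  # local import: pipeline imports us not

    specific_rankings: list[EpicenterRanking] = []
    global_rankings: list[EpicenterRanking] = []
    for rep in range(reps):
        ctrl = perturb_profile(control, direction, max_frac, seed, rep)
        pert = perturb_profile(perturbed, direction, max_frac, seed, rep)
        try:
            result = run_stages(base, ctrl, pert, q=q, top_k=top_k, analyze=analyze)
        except Exception as exc:  # annotate with the repetition index
            raise type(exc)(f"repetition {rep}: {exc}") from exc
        specific, global_ = result.rankings[analyze]
        specific_rankings.append(specific)
        global_rankings.append(global_)
    always, mean_rank, freq = aggregate_rankings(specific_rankings, tuple(top_ks))
    return StabilityReport(
        direction=direction, max_frac=max_frac, reps=reps, seed=seed,
        top_ks=tuple(top_ks), specific_rankings=specific_rankings,
        global_rankings=global_rankings, always_in_top_k=always,
        mean_rank=mean_rank, top_k_frequency=freq)
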
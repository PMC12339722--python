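"""Memory-performance metrics and recall-success classification.

Object recall is scored as correct/incorrect; location recall by the
drop error (Euclidean distance between response and true location),
normalized by ranking within a large sample of potential drop errors
drawn uniformly over the arena. A location recall counts as successful
when its normalized performance exceeds the session median; encoding
segments inherit the success of their paired recall.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Arena",
    "object_recall_performance",
    "normalize_drop_error",
    "classify_recall_success",
    "performance_trend",
]


class Arena:
    """Arena geometry for drop-error normalization.

    ``kind='rect'`` uses ``bounds=(width, height)`` centred on the
    origin; ``kind='disc'`` uses ``bounds=(radius,)``.
    """

    def __init__(self, kind: str = "rect", bounds=(100.0, 100.0)):
        if kind not in ("rect", "disc"):
            raise ValueError("kind must be 'rect' or 'disc'")
        self.kind = kind
        self.bounds = tuple(float(b) for b in bounds)

    def contains(self, point) -> bool:
        x, y = point
        if self.kind == "rect":
            w, h = self.bounds
            return abs(x) <= w / 2 and abs(y) <= h / 2
        (r,) = self.bounds
        return x * x + y * y <= r * r

    def sample(self, n: int, rng) -> np.ndarray:
        if self.kind == "rect":
            w, h = self.bounds
            return rng.uniform([-w / 2, -h / 2], [w / 2, h / 2], size=(n, 2))
        (r,) = self.bounds
        rad = r * np.sqrt(rng.uniform(size=n))
        ang = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])

    @property
    def diameter(self) -> float:
        if self.kind == "rect":
            w, h = self.bounds
            return float(np.hypot(w, h))
        return 2.0 * self.bounds[0]


def object_recall_performance(behavior: pd.DataFrame, scope=None) -> float:
    """Fraction of correctly recalled objects among all object recalls."""
    df = behavior[behavior["kind"] == "object"]
    if scope is not None:
        df = df[df["trial"].isin(scope)]
    if df.empty:
        raise ValueError("no object recalls in scope")
    return float(df["correct"].mean())


def normalize_drop_error(
    drop_error: float,
    arena: Arena,
    true_location,
    n_potential: int = 1_000_000,
    rng=None,
) -> float:
    """Rank a drop error within uniformly sampled potential drop errors.

    Returns the fraction of ``n_potential`` random response locations
    whose distance to the true location strictly exceeds the observed
    drop error: 1 is the best possible response, 0 the worst.
    """
    if drop_error < 0:
        raise ValueError("drop error must be non-negative")
    if not arena.contains(true_location):
        raise ValueError("true location outside arena")
    rng = np.random.default_rng(rng)
    pts = arena.sample(n_potential, rng)
    d = np.hypot(pts[:, 0] - true_location[0], pts[:, 1] - true_location[1])
    return float(np.mean(d > drop_error))


def classify_recall_success(behavior: pd.DataFrame) -> pd.DataFrame:
    """Success flags: object = correct; location = above-median normalized.

    The recall exactly at the median counts as unsuccessful (strict
    inequality). Raises if all normalized values are identical.
    """
    out = behavior.copy()
    success = np.zeros(len(out), dtype=bool)
    obj = out["kind"] == "object"
    success[obj.to_numpy()] = out.loc[obj, "correct"].astype(bool).to_numpy()
    loc = ~obj
    if loc.any():
        vals = out.loc[loc, "normalized"].to_numpy(dtype=float)
        if vals.size >= 2 and np.all(vals == vals[0]):
            raise ValueError("all normalized performances identical: median split undefined")
        success[loc.to_numpy()] = vals > np.median(vals)
    out["success"] = success
    return out


def performance_trend(per_session_behavior: list[pd.DataFrame]) -> dict:
    """First-half vs second-half performance, paired across sessions.

    For each session the trials are split in half (an odd middle trial
    joins the first half); the per-metric means of the two halves are
    compared with a two-sided paired t-test across sessions. Returns
    ``{metric: (t, p, n_sessions)}`` for object accuracy and location
    normalized performance (where present).
    """
    if len(per_session_behavior) < 2:
        raise ValueError("trend test requires >= 2 sessions")
    halves = {"object": ([], []), "location": ([], [])}
    for beh in per_session_behavior:
        trials = np.sort(beh["trial"].unique())
        cut = (trials.size + 1) // 2  # middle trial -> first half
        first, second = set(trials[:cut]), set(trials[cut:])
        for kind, col in (("object", "correct"), ("location", "normalized")):
            sel = beh["kind"] == kind
            if not sel.any():
                continue
            f = beh[sel & beh["trial"].isin(first)][col].astype(float)
            s = beh[sel & beh["trial"].isin(second)][col].astype(float)
            if len(f) and len(s):
                halves[kind][0].append(f.mean())
                halves[kind][1].append(s.mean())
    results = {}
    for kind, (f, s) in halves.items():
        if len(f) >= 2:
            t, p = stats.ttest_rel(f, s)
            results[kind] = (float(t), float(p), len(f))
    return results
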
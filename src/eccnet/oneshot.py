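"""One-shot same/different evaluation protocol.

A target glyph is "learned" from a single presentation and compared to a
test presentation (same glyph or its paired distractor) by Pearson
correlation of network features.  Two metrics are provided:

* ``symmetric`` - correlation between the two scale-pooled feature vectors;
* ``asymmetric`` - the stored target keeps its per-channel feature bank
  (templates at multiple resolutions) while the test is scale-pooled; the
  channel with the highest correlation to the test is chosen.

Per condition, the decision threshold is the one maximizing classification
accuracy over balanced same/distractor trials; d-prime is reported from the
resulting hit and false-alarm rates.  A (size x eccentricity) -> accuracy
map is assembled into an invariance window with an interpolated surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.stats import norm

from .stimuli import FieldCalibration, GlyphSet, StimulusSpec, render_stimulus

__all__ = [
    "REGIMES",
    "UndefinedCorrelationError",
    "ConditionSpec",
    "TrialOutcome",
    "ConditionResult",
    "InvarianceWindow",
    "pearson",
    "symmetric_similarity",
    "asymmetric_similarity",
    "optimal_threshold",
    "dprime",
    "run_condition",
    "build_window",
    "correlation_vs_eccentricity",
]

REGIMES = ("central", "peripheral", "same", "opposite")


class UndefinedCorrelationError(ValueError):
    """Pearson correlation of a constant vector is undefined."""


# ---------------------------------------------------------------------------
# similarity primitives


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson's r between two feature vectors of equal length >= 2."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 elements")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise UndefinedCorrelationError("constant feature vector")
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    try:
        return pearson(a, b)
    except UndefinedCorrelationError:
        warnings.warn("constant feature vector; similarity set to 0", stacklevel=3)
        return 0.0


def symmetric_similarity(target_pooled: np.ndarray, test_pooled: np.ndarray) -> float:
    """Correlation of the two scale-pooled vectors (order-invariant)."""
    return _safe_pearson(target_pooled, test_pooled)


def asymmetric_similarity(
    target_bank: np.ndarray, test_pooled: np.ndarray
) -> tuple[float, int]:
    """Best correlation between any stored per-channel template of the target
    and the scale-pooled test feature; returns (similarity, chosen channel).

    Not symmetric: only the target keeps multi-resolution templates.
    """
    bank = np.asarray(target_bank)
    if bank.ndim != 2:
        raise ValueError("target bank must be (n_channels, D)")
    sims = np.full(bank.shape[0], -np.inf)
    any_defined = False
    for k in range(bank.shape[0]):
        try:
            sims[k] = pearson(bank[k], test_pooled)
            any_defined = True
        except UndefinedCorrelationError:
            sims[k] = 0.0
    if not any_defined:
        raise UndefinedCorrelationError("all stored channels are constant")
    k = int(np.argmax(sims))
    return float(sims[k]), k


def optimal_threshold(
    same_sims: list[float] | np.ndarray, diff_sims: list[float] | np.ndarray
) -> tuple[float, float]:
    """Threshold maximizing accuracy of the rule "same iff similarity > t".

    accuracy(t) = (#{same > t} + #{diff <= t}) / (n_same + n_diff), searched
    over midpoints of the sorted union of similarities plus sentinels below
    and above all values; the maximum is exact.
    """
    same = np.asarray(same_sims, dtype=np.float64)
    diff = np.asarray(diff_sims, dtype=np.float64)
    if same.size == 0 or diff.size == 0:
        raise ValueError("both similarity lists must be non-empty")
    values = np.unique(np.concatenate([same, diff]))
    cands = np.concatenate(
        [[values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0]]
    )
    n = same.size + diff.size
    best_t, best_acc = cands[0], -1.0
    for t in cands:
        acc = (np.count_nonzero(same > t) + np.count_nonzero(diff <= t)) / n
        if acc > best_acc:
            best_t, best_acc = float(t), float(acc)
    return best_t, best_acc


def dprime(
    hit_rate: float, fa_rate: float, n_same: int | None = None, n_diff: int | None = None
) -> float:
    """Signal-detection d' = z(hit) - z(fa).

    Rates of exactly 0 or 1 are undefined under the normal quantile; when
    trial counts are supplied they are corrected with the log-linear rule
    (add 0.5 to the count, 1 to the number of trials).  Without counts, a
    count of 1 is assumed for the correction.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")

    def z(rate: float, n: int | None) -> float:
        if rate in (0.0, 1.0):
            n = 1 if n is None else n
            rate = (rate * n + 0.5) / (n + 1)
        return float(norm.ppf(rate))

    return z(hit_rate, n_same) - z(fa_rate, n_diff)


# ---------------------------------------------------------------------------
# conditions


@dataclass(frozen=True)
class ConditionSpec:
    """One (target size/position, test size/position) condition.

    Sizes in arcmin, eccentricities in signed degrees.  The regime labels
    the learning geometry: central (0 -> D), peripheral (D -> 0), same
    (D -> D), opposite (D -> -D).
    """

    target_size: float
    test_size: float
    target_ecc: float = 0.0
    test_ecc: float = 0.0
    regime: str = "central"
    metric: str = "symmetric"

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.metric not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown metric {self.metric!r}")
        checks = {
            "central": self.target_ecc == 0.0,
            "peripheral": self.test_ecc == 0.0,
            "same": self.target_ecc == self.test_ecc,
            "opposite": self.test_ecc == -self.target_ecc,
        }
        if not checks[self.regime]:
            raise ValueError(
                f"eccentricities ({self.target_ecc}, {self.test_ecc}) inconsistent "
                f"with regime {self.regime!r}"
            )


@dataclass(frozen=True)
class TrialOutcome:
    pair_id: str
    is_same: bool
    similarity: float


@dataclass
class ConditionResult:
    spec: ConditionSpec
    accuracy: float
    threshold: float
    d_prime: float
    hit_rate: float
    fa_rate: float
    similarities_same: list[float]
    similarities_diff: list[float]
    trials: list[TrialOutcome] = dc_field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.similarities_same) + len(self.similarities_diff)


def _similarity(
    metric: str,
    target_feats: tuple[np.ndarray, np.ndarray],
    test_feats: tuple[np.ndarray, np.ndarray],
) -> float:
    t_bank, t_pooled = target_feats
    _, s_pooled = test_feats
    if metric == "symmetric":
        return symmetric_similarity(t_pooled, s_pooled)
    try:
        sim, _ = asymmetric_similarity(t_bank, s_pooled)
    except UndefinedCorrelationError:
        warnings.warn("all stored channels constant; similarity set to 0", stacklevel=2)
        return 0.0
    return sim


def run_condition(
    spec: ConditionSpec,
    pairs: GlyphSet,
    extractor,
    calib: FieldCalibration,
    cache: dict | None = None,
) -> ConditionResult:
    """Evaluate one condition over all glyph pairs with balanced same and
    distractor trials.

    For nonzero eccentricities, presentation side is counterbalanced by
    mirroring the whole trial (target and test) for every other pair.  The
    extractor must expose ``bank_and_pooled(image) -> (bank, pooled)``.

    ``cache`` (optional) memoizes features by (glyph_id, size, ecc) across
    calls; only share one cache across conditions evaluated with the same
    extractor and calibration.
    """
    if len(pairs.pairing) < 2:
        raise ValueError("need at least 2 glyph pairs")

    def feats(glyph_id: str, size: float, ecc: float):
        key = (glyph_id, size, ecc)
        if cache is not None and key in cache:
            return cache[key]
        img = render_stimulus(StimulusSpec(glyph_id, size, ecc), pairs, calib)
        out = extractor.bank_and_pooled(img)
        if cache is not None:
            cache[key] = out
        return out

    same_sims: list[float] = []
    diff_sims: list[float] = []
    trials: list[TrialOutcome] = []
    for i, tid in enumerate(pairs.target_ids):
        sign = 1.0 if i % 2 == 0 else -1.0
        target_feats = feats(tid, spec.target_size, sign * spec.target_ecc)
        for glyph_id, is_same in ((tid, True), (pairs.distractor_of(tid), False)):
            test_feats = feats(glyph_id, spec.test_size, sign * spec.test_ecc)
            sim = _similarity(spec.metric, target_feats, test_feats)
            (same_sims if is_same else diff_sims).append(sim)
            trials.append(TrialOutcome(tid, is_same, sim))
    threshold, accuracy = optimal_threshold(same_sims, diff_sims)
    hit = float(np.mean(np.asarray(same_sims) > threshold))
    fa = float(np.mean(np.asarray(diff_sims) > threshold))
    d = dprime(hit, fa, len(same_sims), len(diff_sims))
    return ConditionResult(
        spec, accuracy, threshold, d, hit, fa, same_sims, diff_sims, trials
    )


# ---------------------------------------------------------------------------
# invariance windows


@dataclass
class InvarianceWindow:
    """(letter size, eccentricity) -> accuracy map with interpolated surface."""

    grid: dict[tuple[float, float], float]
    regime: str
    _interp: LinearNDInterpolator | None = None

    def surface(self, sizes: np.ndarray, eccs: np.ndarray) -> np.ndarray:
        """Interpolated accuracy at arbitrary (size, ecc) points (same shape)."""
        if self._interp is None:
            pts = np.array([[s, e] for s, e in self.grid], dtype=np.float64)
            vals = np.array([self.grid[(s, e)] for s, e in self.grid])
            self._interp = LinearNDInterpolator(pts, vals)
        return self._interp(np.asarray(sizes, dtype=np.float64),
                            np.asarray(eccs, dtype=np.float64))

    def boundary_eccentricity(self, size: float, threshold: float = 0.85) -> float:
        """Eccentricity at which accuracy first crosses below ``threshold``
        for the given size (linear interpolation between measured nodes).

        Returns 0 if accuracy starts below threshold, and the largest tested
        eccentricity if it never drops below it.
        """
        row = sorted(
            (abs(e), a) for (s, e), a in self.grid.items() if s == size
        )
        if not row:
            raise ValueError(f"no nodes measured at size {size}")
        eccs = [e for e, _ in row]
        accs = [a for _, a in row]
        if accs[0] < threshold:
            return 0.0
        for (e0, a0), (e1, a1) in zip(row, row[1:]):
            if a1 < threshold <= a0:
                if a0 == a1:
                    return e1
                return e0 + (a0 - threshold) / (a0 - a1) * (e1 - e0)
        return eccs[-1]


def build_window(
    results: dict[tuple[float, float], "ConditionResult | float"], regime: str
) -> InvarianceWindow:
    """Assemble measured condition accuracies into an invariance window.

    Node keys are (size arcmin, eccentricity deg).  The interpolated surface
    uses linear barycentric interpolation on the measured nodes (values at
    the nodes are exact); at least 3 non-collinear nodes are required.
    """
    grid = {
        k: (v.accuracy if isinstance(v, ConditionResult) else float(v))
        for k, v in results.items()
    }
    if len(grid) < 3:
        raise ValueError("need at least 3 grid nodes for interpolation")
    pts = np.array(list(grid), dtype=np.float64)
    if np.linalg.matrix_rank(pts - pts[0]) < 2:
        raise ValueError("grid nodes are collinear; cannot interpolate a surface")
    return InvarianceWindow(grid, regime)


def correlation_vs_eccentricity(
    pairs: GlyphSet,
    size: float,
    eccentricities: list[float],
    extractor,
    calib: FieldCalibration,
    metric: str = "asymmetric",
) -> pd.DataFrame:
    """Mean same-glyph feature correlation between presentation at fixation
    and presentation at each eccentricity (the raw-similarity check that the
    representation itself degrades with eccentricity)."""
    center_feats = {}
    for tid in pairs.target_ids:
        img = render_stimulus(StimulusSpec(tid, size, 0.0), pairs, calib)
        center_feats[tid] = extractor.bank_and_pooled(img)
    rows = []
    for ecc in eccentricities:
        sims = []
        for i, tid in enumerate(pairs.target_ids):
            sign = 1.0 if i % 2 == 0 else -1.0
            img = render_stimulus(StimulusSpec(tid, size, sign * ecc), pairs, calib)
            feats = extractor.bank_and_pooled(img)
            sims.append(_similarity(metric, center_feats[tid], feats))
        rows.append({"size_arcmin": size, "eccentricity_deg": ecc,
                     "mean_correlation": float(np.mean(sims)), "n_pairs": len(sims)})
    return pd.DataFrame(rows)
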
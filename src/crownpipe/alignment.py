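"""One-to-one alignment of field-measured stems with remotely sensed crowns.

Stems and crowns live in the same projected coordinate system but come
from different surveys, so within each plot the stems first get a
systematic-offset correction (translating the stem centroid onto the crown
centroid).  Each candidate stem-crown pairing is then scored by a
dimensionless cost

    C = ((D - D_hat) / D_rms)^2 + ((X - X_hat) / X_rms)^2
        + ((Y - Y_hat) / Y_rms)^2

where D is the crown diameter implied by the crown's area under a circular
assumption, D_hat is the diameter predicted from the stem by a fitted
allometric regression, X/Y are crown coordinates, X_hat/Y_hat stem
coordinates, and the RMS normalizers are measured on training pairs with
known correspondence.  The alignment of a plot is the one-to-one matching
minimizing the total cost, solved exactly as a linear assignment problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

from .io_core import CrownRecord, StemRecord

__all__ = [
    "AllometricModel",
    "AlignmentNormalization",
    "AlignmentResult",
    "cluster_stems_to_plots",
    "correct_offset",
    "diameter_from_area",
    "fit_allometry",
    "compute_normalization",
    "pair_cost",
    "optimal_pairing",
    "alignment_accuracy",
]

Predictor = Literal["stem_diameter_cm", "stem_height_m"]


@dataclass
class AllometricModel:
    """Linear model predicting crown diameter (m) from a stem measurement."""

    slope: float
    intercept: float
    r_squared: float
    predictor: Predictor = "stem_diameter_cm"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def predict(self, stem: StemRecord) -> float:
        """Predicted crown diameter D_hat for a stem, m."""
        x = getattr(stem, self.predictor)
        return self.slope * x + self.intercept


@dataclass
class AlignmentNormalization:
    """RMS scales (m) making the three cost residuals dimensionless."""

    d_rms: float
    x_rms: float
    y_rms: float

    def __post_init__(self) -> None:
        for name in ("d_rms", "x_rms", "y_rms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class AlignmentResult:
    """A one-to-one stem-crown matching with its costs."""

    pairs: list[tuple[str, str]]
    total_cost: float
    per_pair_cost: dict[tuple[str, str], float]
    unmatched_stems: list[str] = field(default_factory=list)
    unmatched_crowns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        stems = [s for s, _ in self.pairs]
        crowns = [c for _, c in self.pairs]
        if len(set(stems)) != len(stems) or len(set(crowns)) != len(crowns):
            raise ValueError("each stem_id and crown_id may appear at most once")
        if not math.isclose(
            self.total_cost, sum(self.per_pair_cost.values()), abs_tol=1e-9
        ):
            raise ValueError("total_cost does not equal the sum of pair costs")


def cluster_stems_to_plots(
    stems: Sequence[StemRecord], crowns: Sequence[CrownRecord]
) -> list[StemRecord]:
    """Assign each stem the plot of its nearest crown (Euclidean distance).

    Nearest-crown ties are broken toward the smaller crown_id.  Returns new
    records; the inputs are not modified.
    """
    if not crowns:
        raise ValueError("at least one crown is required")
    out: list[StemRecord] = []
    for stem in stems:
        best = min(
            crowns,
            key=lambda c: (
                (c.x_pos - stem.x_pos) ** 2 + (c.y_pos - stem.y_pos) ** 2,
                c.crown_id,
            ),
        )
        out.append(replace(stem, plot_id=best.plot_id))
    return out


def correct_offset(
    stems: Sequence[StemRecord], crowns: Sequence[CrownRecord]
) -> list[StemRecord]:
    """Remove a plot-wide systematic positioning offset from the stems.

    Every stem is shifted by the difference between the crown-group and
    stem-group centroid, so the shifted stem centroid coincides with the
    crown centroid.  Returns new records.
    """
    if not stems or not crowns:
        raise ValueError("both stem and crown lists must be non-empty")
    dx = float(np.mean([c.x_pos for c in crowns]) - np.mean([s.x_pos for s in stems]))
    dy = float(np.mean([c.y_pos for c in crowns]) - np.mean([s.y_pos for s in stems]))
    return [replace(s, x_pos=s.x_pos + dx, y_pos=s.y_pos + dy) for s in stems]


def diameter_from_area(area_m2: float) -> float:
    """Crown diameter (m) implied by crown area under a circular assumption."""
    if area_m2 < 0:
        raise ValueError(f"area must be >= 0, got {area_m2}")
    return 2.0 * math.sqrt(area_m2 / math.pi)


def fit_allometry(
    training: Sequence[tuple[float, float]],
    predictor: Predictor = "stem_diameter_cm",
) -> AllometricModel:
    """Ordinary least-squares fit of crown diameter on a stem measurement.

    ``training`` holds (predictor value, crown diameter m) points; at
    least 3 points with a non-constant predictor are required.
    """
    if len(training) < 3:
        raise ValueError("at least 3 training points are required")
    x = np.asarray([t[0] for t in training], dtype=float)
    y = np.asarray([t[1] for t in training], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; cannot fit a regression")
    fit = linregress(x, y)
    # rvalue**2 is the coefficient of determination for simple OLS
    return AllometricModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0,
        predictor=predictor,
    )


def compute_normalization(
    training: Sequence[tuple[StemRecord, CrownRecord]],
    model: AllometricModel,
) -> AlignmentNormalization:
    """RMS residual scales measured on training pairs with known truth.

    ``d_rms`` is the RMS of (crown diameter - predicted diameter) over the
    pairs; ``x_rms``/``y_rms`` are the RMS coordinate residuals of paired
    stems vs crowns.  A zero RMS (degenerate, perfectly aligned training
    data) raises; supply an explicit floor via
    :class:`AlignmentNormalization` if that is really intended.
    """
    if len(training) < 2:
        raise ValueError("at least 2 training pairs are required")
    d_res = [
        diameter_from_area(crown.area_m2) - model.predict(stem)
        for stem, crown in training
    ]
    x_res = [crown.x_pos - stem.x_pos for stem, crown in training]
    y_res = [crown.y_pos - stem.y_pos for stem, crown in training]
    rms = {
        "d_rms": float(np.sqrt(np.mean(np.square(d_res)))),
        "x_rms": float(np.sqrt(np.mean(np.square(x_res)))),
        "y_rms": float(np.sqrt(np.mean(np.square(y_res)))),
    }
    zero = [k for k, v in rms.items() if v == 0.0]
    if zero:
        raise ValueError(
            f"degenerate training data: {zero} are exactly 0; construct an "
            "AlignmentNormalization with an explicit floor (e.g. 1e-6 m) "
            "if this is intended"
        )
    return AlignmentNormalization(**rms)


def pair_cost(
    stem: StemRecord,
    crown: CrownRecord,
    model: AllometricModel,
    norm: AlignmentNormalization,
    position_only: bool = False,
) -> float:
    """Dimensionless cost of pairing one stem with one crown.

    With ``position_only=True`` the diameter term is dropped, reproducing a
    position-only benchmark matcher.
    """
    d = diameter_from_area(crown.area_m2)
    d_hat = model.predict(stem)
    cost = ((crown.x_pos - stem.x_pos) / norm.x_rms) ** 2 + (
        (crown.y_pos - stem.y_pos) / norm.y_rms
    ) ** 2
    if not position_only:
        cost += ((d - d_hat) / norm.d_rms) ** 2
    return float(cost)


def optimal_pairing(
    stems: Sequence[StemRecord],
    crowns: Sequence[CrownRecord],
    model: AllometricModel,
    norm: AlignmentNormalization,
    position_only: bool = False,
) -> AlignmentResult:
    """Minimum-total-cost one-to-one matching of stems to crowns.

    Solved exactly as a rectangular linear assignment problem; the smaller
    side is fully matched and the surplus reported unmatched.
    """
    if not stems or not crowns:
        raise ValueError("both stem and crown lists must be non-empty")
    cost = np.array(
        [
            [pair_cost(s, c, model, norm, position_only) for c in crowns]
            for s in stems
        ]
    )
    rows, cols = linear_sum_assignment(cost)
    pairs = [(stems[i].stem_id, crowns[j].crown_id) for i, j in zip(rows, cols)]
    per_pair = {
        (stems[i].stem_id, crowns[j].crown_id): float(cost[i, j])
        for i, j in zip(rows, cols)
    }
    matched_stems = {p[0] for p in pairs}
    matched_crowns = {p[1] for p in pairs}
    return AlignmentResult(
        pairs=pairs,
        total_cost=float(cost[rows, cols].sum()),
        per_pair_cost=per_pair,
        unmatched_stems=[s.stem_id for s in stems if s.stem_id not in matched_stems],
        unmatched_crowns=[
            c.crown_id for c in crowns if c.crown_id not in matched_crowns
        ],
    )


def alignment_accuracy(
    result: AlignmentResult, truth: Sequence[tuple[str, str]]
) -> float:
    """Fraction of true stem-crown pairs exactly reproduced by the matching."""
    if not truth:
        raise ValueError("truth pairing list must be non-empty")
    produced = set(result.pairs)
    return sum(1 for t in truth if tuple(t) in produced) / len(truth)
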
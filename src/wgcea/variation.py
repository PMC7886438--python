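"""Cross-trial variation screen: what correlates with cost-effectiveness?

With six trials as data points, the screen computes pairwise Pearson correlations of
the cost-effectiveness ratio and the unit cost against effectiveness (LYS), coverage,
scale (live births, population) and intensity (number of groups), with two-sided
p-values from the exact t reference distribution (n = 6 makes the normal
approximation materially wrong). Significance is declared at p < 0.05, with no
multiple-testing correction, matching the descriptive intent of the screen.

Scale and intensity denominators use the factorial-halved convention by default
(the women's-groups-only arm of the two Malawi trials); pass
``factorial_halving=False`` to screen against full-area figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .fixtures import TRIAL_IDS, load_all

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def pearson(x: Sequence[float], y: Sequence[float], labels: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with an exact two-sided t test.

    Implemented from the covariance definition; the p-value transforms r to
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sx = float(np.sqrt(np.sum(xd * xd)))
    sy = float(np.sqrt(np.sum(yd * yd)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in one of the inputs")
    r = float(np.sum(xd * yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(variable_pair=labels, r=r, p_value=p, n=n)


# (x, y) label pairs of the screen grid: CER against unit cost, effectiveness,
# coverage, scale and intensity; unit cost against coverage, scale and intensity.
SCREEN_PAIRS = [
    ("cost_per_live_birth", "cer"),
    ("neonatal_lys", "cer"),
    ("coverage", "cer"),
    ("live_births", "cer"),
    ("population", "cer"),
    ("n_groups", "cer"),
    ("coverage", "cost_per_live_birth"),
    ("live_births", "cost_per_live_birth"),
    ("n_groups", "cost_per_live_birth"),
]


def _screen_vectors(factorial_halving: bool) -> dict[str, list[float]]:
    fixtures = load_all()
    vec: dict[str, list[float]] = {k: [] for k in
        ("cer", "cost_per_live_birth", "neonatal_lys", "coverage", "live_births", "population", "n_groups")}
    for tid in TRIAL_IDS:
        profile, reported = fixtures[tid]
        vec["cer"].append(reported.cer)
        vec["cost_per_live_birth"].append(reported.cost_per_live_birth)
        vec["neonatal_lys"].append(reported.neonatal_lys)
        vec["coverage"].append(profile.coverage)
        vec["live_births"].append(profile.effective_live_births(factorial_halving))
        vec["population"].append(profile.effective_population(factorial_halving))
        vec["n_groups"].append(profile.effective_n_groups(factorial_halving))
    return vec


def variation_screen(
    trials: dict[str, dict[str, float]] | None = None,
    factorial_halving: bool = True,
) -> list[CorrelationResult]:
    """Run the full correlation grid.

    With no argument the packaged six-trial reference data are screened. A custom
    screen passes ``trials`` as {trial_id: {variable: value}} covering the grid
    variables; at least three trials are required.
    """
    if trials is None:
        vec = _screen_vectors(factorial_halving)
    else:
        if len(trials) < 3:
            raise ValueError("need at least 3 trials")
        names = sorted(trials)
        keys = {k for row in trials.values() for k in row}
        vec = {k: [trials[t][k] for t in names] for k in keys}
    return [pearson(vec[x], vec[y], labels=(x, y)) for x, y in SCREEN_PAIRS if x in vec and y in vec]


def scatter_plots(results_dir, factorial_halving: bool = True) -> list[str]:
    """Optional scatter plots for each screened pair (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    vec = _screen_vectors(factorial_halving)
    outdir = Path(results_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for x, y in SCREEN_PAIRS:
        res = pearson(vec[x], vec[y], labels=(x, y))
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(vec[x], vec[y])
        ax.set_xlabel(x)
        ax.set_ylabel(y)
        ax.set_title(f"r = {res.r:.2f}, p = {res.p_value:.2f}")
        fig.tight_layout()
        path = outdir / f"scatter_{y}_vs_{x}.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(str(path))
    return written
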
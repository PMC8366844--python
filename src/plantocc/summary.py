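"""Posterior summaries and decision rules.

Point estimates are the KDE mode (MAP) and the mean (EAP).  Interval
summaries are the highest density interval (HDI, default 89% mass) and
equal-tailed credible intervals (95% and 90%).  The HDI+ROPE rule declares a
coefficient significant when its entire HDI falls outside a region of
practical equivalence around zero, [-0.1, 0.1] by default; the CI rule
declares significance when the 95% interval excludes zero.  Both rules are
always reported side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "RopeSpec",
    "map_estimate",
    "hdi",
    "credible_interval",
    "rope_decision",
    "ci_significance",
    "rhat",
    "posterior_predictive",
    "summarize_draws",
    "summarize_coefficients",
    "summarize_species",
]


@dataclass
class RopeSpec:
    """Region of practical equivalence around a null effect (logit scale)."""

    lower: float = -0.1
    upper: float = 0.1

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("ROPE lower bound must be below the upper bound")


def map_estimate(draws: np.ndarray, grid_size: int = 2048) -> float:
    """Posterior mode via a Gaussian KDE (Silverman bandwidth) on a fine grid."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError(
            "MAP estimation needs at least 100 draws; run the sampler longer"
        )
    if np.ptp(x) == 0.0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def hdi(draws: np.ndarray, mass: float = 0.89) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` draws.

    Among equally short windows the one starting at the smallest value wins.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty draw vector")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lower start
    return float(x[i]), float(x[i + m - 1])


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed quantile interval."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly in (0, 1)")
    x = np.asarray(draws, dtype=float).ravel()
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [a, 1.0 - a])
    return float(lo), float(hi)


def rope_decision(
    draws: np.ndarray,
    rope: RopeSpec | None = None,
    mass: float = 0.89,
    convention: str = "draws",
) -> tuple[float, bool]:
    """Fraction of the HDI inside the ROPE and the HDI+ROPE verdict.

    ``convention="draws"`` (default) counts the fraction of draws inside the
    HDI that also fall in the ROPE; ``"length"`` uses interval-overlap
    geometry.  The verdict is significant iff the HDI is entirely disjoint
    from the ROPE (both conventions agree there).
    """
    rope = rope or RopeSpec()
    x = np.asarray(draws, dtype=float).ravel()
    lo, hi = hdi(x, mass=mass)
    if convention == "draws":
        inside_hdi = x[(x >= lo) & (x <= hi)]
        in_rope = (inside_hdi >= rope.lower) & (inside_hdi <= rope.upper)
        pct = float(in_rope.mean()) if inside_hdi.size else 0.0
    elif convention == "length":
        overlap = max(0.0, min(hi, rope.upper) - max(lo, rope.lower))
        pct = overlap / (hi - lo) if hi > lo else float(rope.lower <= lo <= rope.upper)
    else:
        raise ValueError("convention must be 'draws' or 'length'")
    significant = hi < rope.lower or lo > rope.upper
    return pct, bool(significant)


def ci_significance(draws: np.ndarray, level: float = 0.95) -> bool:
    """True iff zero lies outside the equal-tailed credible interval."""
    lo, hi = credible_interval(draws, level=level)
    return bool(lo > 0.0 or hi < 0.0)


def rhat(chains: np.ndarray) -> float:
    """Rank-normalized split-Rhat of one parameter, shape (chains, draws)."""
    import arviz as az

    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("rhat needs a (chains, draws) array with >= 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(az.convert_to_dataset(arr[:, :, None]))
    return float(np.asarray(r["x"]).ravel()[0])


def summarize_draws(
    draws: np.ndarray,
    name: str = "",
    rope: RopeSpec | None = None,
    hdi_mass: float = 0.89,
    rope_convention: str = "draws",
) -> dict:
    """One summary row: MAP, EAP, HDI, CIs, %HDI-in-ROPE, both verdicts."""
    x = np.asarray(draws, dtype=float).ravel()
    h_lo, h_hi = hdi(x, mass=hdi_mass)
    c95 = credible_interval(x, 0.95)
    c90 = credible_interval(x, 0.90)
    pct, sig_rope = rope_decision(
        x, rope=rope, mass=hdi_mass, convention=rope_convention
    )
    return {
        "parameter": name,
        "MAP": map_estimate(x),
        "hdi_lower": h_lo,
        "hdi_upper": h_hi,
        "EAP": float(x.mean()),
        "ci95_lower": c95[0],
        "ci95_upper": c95[1],
        "ci90_lower": c90[0],
        "ci90_upper": c90[1],
        "pct_hdi_in_rope": pct,
        "significant_rope": sig_rope,
        "significant_ci": ci_significance(x, 0.95),
    }


def summarize_species(fit, species_labels: list[str] | None = None) -> pd.DataFrame:
    """Per-species frequency-of-occurrence table (Model 1's main output).

    Rows summarize inv-logit(alpha_j): MAP with 89% HDI and EAP with 95% CI.
    """
    freq = fit.stacked("freq")
    labels = species_labels or fit.meta.get("species_labels")
    if labels is None:
        labels = [f"species_{j}" for j in range(freq.shape[1])]
    rows = []
    for j, label in enumerate(labels):
        x = freq[:, j]
        h = hdi(x, 0.89)
        c = credible_interval(x, 0.95)
        rows.append(
            {
                "species_id": label,
                "MAP": map_estimate(x),
                "hdi_lower": h[0],
                "hdi_upper": h[1],
                "EAP": float(x.mean()),
                "ci95_lower": c[0],
                "ci95_upper": c[1],
            }
        )
    return pd.DataFrame(rows)


def summarize_coefficients(
    fit,
    rope: RopeSpec | None = None,
    hdi_mass: float = 0.89,
    rope_convention: str = "draws",
) -> pd.DataFrame:
    """Fixed-effect coefficient table (Model 2's main output).

    One row per environmental coefficient (beta) and species-level
    coefficient (eps: log body mass, then PV axes), in design order.
    """
    env_names = fit.meta.get("env_names") or []
    sp_names = fit.meta.get("sp_names") or []
    rows = []
    beta = fit.stacked("beta")
    for k in range(beta.shape[1]):
        name = env_names[k] if k < len(env_names) else f"beta[{k}]"
        rows.append(
            summarize_draws(beta[:, k], name, rope, hdi_mass, rope_convention)
        )
    eps = fit.stacked("eps")
    for k in range(eps.shape[1]):
        name = sp_names[k] if k < len(sp_names) else f"eps[{k}]"
        rows.append(
            summarize_draws(eps[:, k], name, rope, hdi_mass, rope_convention)
        )
    return pd.DataFrame(rows)


def posterior_predictive(
    fit,
    records,
    seed: int = 0,
    max_draws: int = 500,
) -> pd.DataFrame:
    """Replicate y for reported records from the posterior of p.

    For a subset of posterior draws, simulates y_rep ~ Binomial(N_i, p_i) and
    reports per-record mean and central quantiles of y_rep plus whether the
    observed y falls inside the central 95% of its replicate distribution.
    The ``covered_95`` column's mean is the PPC coverage statistic.
    """
    rng = np.random.default_rng(seed)
    p = fit.stacked("p")  # (draws, n_records)
    n_draws = p.shape[0]
    take = min(max_draws, n_draws)
    idx = rng.choice(n_draws, size=take, replace=False)
    p_sub = p[idx]
    rows = []
    for i, rec in enumerate(records):
        if rec.y is None:
            continue
        y_rep = rng.binomial(rec.N, p_sub[:, i])
        q = np.quantile(y_rep, [0.025, 0.25, 0.5, 0.75, 0.975])
        rows.append(
            {
                "record_id": rec.record_id,
                "species_id": rec.species_id,
                "N": rec.N,
                "y_obs": rec.y,
                "y_rep_mean": float(y_rep.mean()),
                "y_rep_q2.5": q[0],
                "y_rep_q25": q[1],
                "y_rep_median": q[2],
                "y_rep_q75": q[3],
                "y_rep_q97.5": q[4],
                "covered_95": bool(q[0] <= rec.y <= q[4]),
            }
        )
    return pd.DataFrame(rows)
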
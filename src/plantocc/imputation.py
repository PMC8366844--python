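"""Imputation of mentioned-but-unquantified occurrence counts.

Some studies state that plant material was present without giving the count.
Two schemes fill those records: (a) random — an occurrence frequency drawn
uniformly from the grid 0.01, 0.02, ..., 1.00; (b) posterior — a frequency
drawn from the record's own posterior of p under the non-imputed fit, after
binning that posterior into a discrete distribution and dropping the zero
bin (a mention implies occurrence).  In both cases the imputed count is
round(p * N), clamped to [1, N].

Imputed fits are repeated over replicates with distinct seeds, thinned 1/2
and pooled by concatenating draws; the reporting probability psi is never
re-estimated on imputed data but resampled from the non-imputed posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from plantocc.data import DietRecord
from plantocc.models import MCMCConfig
from plantocc.nuts import ModelFit, fit as nuts_fit, thin

__all__ = [
    "ImputedDataset",
    "PosteriorBinDistribution",
    "impute_random",
    "bin_posterior",
    "bin_posteriors_for_mentioned",
    "impute_from_posterior",
    "replicate_fit_and_pool",
]


@dataclass
class ImputedDataset:
    """One replicate of the record table with mentioned rows filled in."""

    records: list[DietRecord]
    replicate_index: int
    method: str  # "random" | "posterior"
    seed: int
    imputed_ids: list[str] = field(default_factory=list)


@dataclass
class PosteriorBinDistribution:
    """Discrete distribution over nonzero frequency bins of width 0.005/0.01."""

    bin_edges: np.ndarray  # (k+1,) edges of the retained (nonzero) bins
    bin_probabilities: np.ndarray  # (k,) sum to 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_probabilities = np.asarray(self.bin_probabilities, dtype=float)
        if np.any(self.bin_probabilities < 0):
            raise ValueError("bin probabilities must be non-negative")
        if not np.isclose(self.bin_probabilities.sum(), 1.0):
            raise ValueError("bin probabilities must sum to 1")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.choice(self.midpoints, p=self.bin_probabilities))


def _impute_count(p: float, n: int) -> int:
    """round-half-up of p*N, clamped to [1, N] (a mention implies y >= 1)."""
    return int(min(max(np.floor(p * n + 0.5), 1), n))


def impute_random(records: list[DietRecord], seed: int) -> ImputedDataset:
    """Fill mentioned records with frequencies uniform on {0.01, ..., 1.00}."""
    rng = np.random.default_rng(seed)
    out = []
    imputed_ids = []
    for rec in records:
        if rec.mentioned and not rec.reported:
            p = rng.integers(1, 101) / 100.0
            new = dc_replace(rec, y=_impute_count(p, rec.N), mentioned=False)
            imputed_ids.append(rec.record_id)
            out.append(new)
        else:
            out.append(rec)
    if not imputed_ids:
        warnings.warn("no mentioned records found; imputation is a no-op")
    return ImputedDataset(
        records=out, replicate_index=0, method="random", seed=seed,
        imputed_ids=imputed_ids,
    )


def bin_posterior(
    fit: ModelFit,
    record_index: int,
    bin_width: float = 0.01,
) -> PosteriorBinDistribution:
    """Bin the posterior of p for one record into a discrete distribution.

    The histogram covers (0, 1] at uniform width; the bin containing zero is
    excluded before renormalization, since only nonzero frequencies are
    admissible for a record that mentions plants.
    """
    if "p" not in fit.draws:
        raise ValueError("fit carries no per-record p draws")
    draws = fit.stacked("p")[:, record_index]
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(draws, bins=edges)
    counts = counts.astype(float)
    counts[0] = 0.0  # drop the zero bin
    total = counts.sum()
    if total == 0:
        raise ValueError(
            "all posterior draws fall in the zero bin; use a finer bin width"
        )
    return PosteriorBinDistribution(
        bin_edges=edges, bin_probabilities=counts / total
    )


def bin_posteriors_for_mentioned(
    records: list[DietRecord],
    source_fit: ModelFit,
    bin_width: float = 0.01,
    pooled: bool = False,
) -> dict[str, PosteriorBinDistribution]:
    """Bin distributions for every mentioned record, keyed by record_id.

    ``pooled=True`` bins the p draws of all mentioned records together and
    assigns the same distribution to each (the alternative reading of a
    record-indexed p); the default is per-record.
    """
    mentioned_idx = [
        i for i, r in enumerate(records) if r.mentioned and not r.reported
    ]
    if pooled and mentioned_idx:
        draws = source_fit.stacked("p")[:, mentioned_idx].ravel()
        n_bins = int(round(1.0 / bin_width))
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        counts, _ = np.histogram(draws, bins=edges)
        counts = counts.astype(float)
        counts[0] = 0.0
        if counts.sum() == 0:
            raise ValueError("all pooled draws fall in the zero bin")
        shared = PosteriorBinDistribution(edges, counts / counts.sum())
        return {records[i].record_id: shared for i in mentioned_idx}
    return {
        records[i].record_id: bin_posterior(source_fit, i, bin_width)
        for i in mentioned_idx
    }


def impute_from_posterior(
    records: list[DietRecord],
    bins: dict[str, PosteriorBinDistribution],
    seed: int,
) -> ImputedDataset:
    """Fill mentioned records by sampling p from their bin distributions.

    The sampled bin is represented by its midpoint; y = round(p*N) clamped
    to [1, N].
    """
    rng = np.random.default_rng(seed)
    out = []
    imputed_ids = []
    for rec in records:
        if rec.mentioned and not rec.reported:
            if rec.record_id not in bins:
                raise ValueError(f"no bin distribution for record {rec.record_id!r}")
            p = bins[rec.record_id].sample(rng)
            out.append(dc_replace(rec, y=_impute_count(p, rec.N), mentioned=False))
            imputed_ids.append(rec.record_id)
        else:
            out.append(rec)
    if not imputed_ids:
        warnings.warn("no mentioned records found; imputation is a no-op")
    return ImputedDataset(
        records=out, replicate_index=0, method="posterior", seed=seed,
        imputed_ids=imputed_ids,
    )


def replicate_fit_and_pool(
    records: list[DietRecord],
    model_factory,
    method: str,
    config: MCMCConfig,
    psi_source: ModelFit | None = None,
    n_replicates: int = 10,
    bin_width: float = 0.01,
    thin_rate: float = 0.5,
    pooled_bins: bool = False,
) -> ModelFit:
    """Impute, fit and pool over replicates.

    Each replicate imputes with its own seed, fits by NUTS, is thinned at
    ``thin_rate`` and contributes its post-warmup draws to the pooled
    posterior (a plain concatenation — draws are not reweighted).  psi draws
    are resampled from ``psi_source`` rather than estimated, since the
    imputed data carry no information about the reporting process.

    ``model_factory(records) -> model`` must build the (psi-free) model for a
    fully-imputed record list.
    """
    if method not in ("random", "posterior"):
        raise ValueError("method must be 'random' or 'posterior'")
    if psi_source is None:
        raise ValueError("a non-imputed psi_source fit is required for pooling")
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(n_replicates)
    bins = None
    if method == "posterior":
        bins = bin_posteriors_for_mentioned(
            records, psi_source, bin_width=bin_width, pooled=pooled_bins
        )
    psi_draws_source = psi_source.stacked("psi")[:, 0]

    replicate_fits = []
    replicate_diag = []
    for r, stream in enumerate(streams):
        state = stream.generate_state(2)
        imp_seed = int(state[0] % (2**31))
        fit_seed = int(state[1] % (2**31))
        if method == "random":
            imputed = impute_random(records, seed=imp_seed)
        else:
            imputed = impute_from_posterior(records, bins, seed=imp_seed)
        imputed.replicate_index = r
        model = model_factory(imputed.records)
        rep_config = MCMCConfig(
            chains=config.chains,
            iterations=config.iterations,
            warmup=config.warmup,
            thin=config.thin,
            seed=fit_seed,
            rhat_threshold=config.rhat_threshold,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
        )
        rep_fit = nuts_fit(model, rep_config)
        rep_fit = thin(rep_fit, thin_rate)
        # attach psi resampled from the non-imputed posterior
        rng = np.random.default_rng(stream.spawn(1)[0])
        c, m = rep_fit.n_chains, rep_fit.n_draws
        rep_fit.draws["psi"] = rng.choice(
            psi_draws_source, size=(c, m, 1), replace=True
        )
        replicate_fits.append(rep_fit)
        replicate_diag.append(
            {
                "replicate": r,
                "imputation_seed": imp_seed,
                "fit_seed": fit_seed,
                "rhat": rep_fit.diagnostics.get("rhat", {}),
                "divergences": rep_fit.diagnostics.get("divergences", []),
                "converged": rep_fit.converged,
            }
        )
        if not rep_fit.converged:
            warnings.warn(f"replicate {r} flagged non-converged; pooling proceeds")

    pooled = {
        key: np.concatenate([f.draws[key] for f in replicate_fits], axis=1)
        for key in replicate_fits[0].draws
    }
    return ModelFit(
        draws=pooled,
        config=config,
        diagnostics={
            "replicates": replicate_diag,
            "rhat": {
                key: max(d["rhat"].get(key, float("nan")) for d in replicate_diag)
                for key in replicate_fits[0].diagnostics.get("rhat", {})
            },
            "method": method,
        },
        meta={"n_replicates": n_replicates, "method": method},
    )
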
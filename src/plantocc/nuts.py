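"""No-U-Turn sampler (NUTS) with dual-averaging step-size adaptation.

A Hamiltonian Monte Carlo variant that simulates leapfrog trajectories whose
length doubles until the path starts to turn back on itself, then draws the
next state from the trajectory with multinomial weights.  Step size is tuned
during warmup by dual averaging toward a target acceptance statistic, and a
diagonal mass matrix is estimated from mid-warmup draws.

The sampler consumes any model object exposing ``dim``,
``logp_grad(z) -> (logp, grad)``, ``constrain_batch(Z)`` and
``initial_position(rng)`` over an unconstrained parameter vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from plantocc.models import MCMCConfig

__all__ = ["ModelFit", "fit", "thin", "sample_chain"]

_MAX_ENERGY_ERROR = 1000.0  # leapfrog energy error treated as a divergence


@dataclass
class _Tree:
    z_minus: np.ndarray
    r_minus: np.ndarray
    grad_minus: np.ndarray
    z_plus: np.ndarray
    r_plus: np.ndarray
    grad_plus: np.ndarray
    proposal: np.ndarray
    proposal_logp: float
    proposal_grad: np.ndarray
    log_sum_w: float
    rho: np.ndarray
    divergent: bool
    turning: bool
    sum_accept: float
    n_leapfrog: int


class _NutsKernel:
    def __init__(self, logp_grad, inv_mass: np.ndarray, max_treedepth: int,
                 rng: np.random.Generator):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.sqrt_mass = np.sqrt(1.0 / inv_mass)
        self.max_treedepth = max_treedepth
        self.rng = rng

    def _kinetic(self, r: np.ndarray) -> float:
        return 0.5 * float(r @ (self.inv_mass * r))

    def _leapfrog(self, z, r, grad, step):
        r1 = r + 0.5 * step * grad
        z1 = z + step * (self.inv_mass * r1)
        logp1, grad1 = self.logp_grad(z1)
        r1 = r1 + 0.5 * step * grad1
        return z1, r1, logp1, grad1

    def _turning(self, rho, r_minus, r_plus) -> bool:
        v_minus = self.inv_mass * r_minus
        v_plus = self.inv_mass * r_plus
        return (rho @ v_minus) <= 0 or (rho @ v_plus) <= 0

    def _leaf(self, z, r, grad, step, direction, joint0) -> _Tree:
        z1, r1, logp1, grad1 = self._leapfrog(z, r, grad, direction * step)
        joint = logp1 - self._kinetic(r1)
        logw = joint - joint0
        divergent = not np.isfinite(joint) or (logw < -_MAX_ENERGY_ERROR)
        accept = float(np.exp(min(0.0, logw))) if np.isfinite(logw) else 0.0
        return _Tree(
            z_minus=z1, r_minus=r1, grad_minus=grad1,
            z_plus=z1, r_plus=r1, grad_plus=grad1,
            proposal=z1, proposal_logp=logp1, proposal_grad=grad1,
            log_sum_w=logw if np.isfinite(logw) else -np.inf,
            rho=r1.copy(), divergent=divergent, turning=False,
            sum_accept=accept, n_leapfrog=1,
        )

    def _build(self, depth, z, r, grad, step, direction, joint0) -> _Tree:
        if depth == 0:
            return self._leaf(z, r, grad, step, direction, joint0)
        first = self._build(depth - 1, z, r, grad, step, direction, joint0)
        if first.divergent or first.turning:
            return first
        if direction == 1:
            second = self._build(
                depth - 1, first.z_plus, first.r_plus, first.grad_plus,
                step, direction, joint0,
            )
            first.z_plus, first.r_plus, first.grad_plus = (
                second.z_plus, second.r_plus, second.grad_plus,
            )
        else:
            second = self._build(
                depth - 1, first.z_minus, first.r_minus, first.grad_minus,
                step, direction, joint0,
            )
            first.z_minus, first.r_minus, first.grad_minus = (
                second.z_minus, second.r_minus, second.grad_minus,
            )
        total = np.logaddexp(first.log_sum_w, second.log_sum_w)
        if np.isfinite(second.log_sum_w):
            if np.log(self.rng.uniform()) < second.log_sum_w - total:
                first.proposal = second.proposal
                first.proposal_logp = second.proposal_logp
                first.proposal_grad = second.proposal_grad
        first.log_sum_w = total
        first.rho = first.rho + second.rho
        first.sum_accept += second.sum_accept
        first.n_leapfrog += second.n_leapfrog
        first.divergent = second.divergent
        first.turning = second.turning or self._turning(
            first.rho, first.r_minus, first.r_plus
        )
        return first

    def step(self, z, logp, grad, step_size):
        """One NUTS transition; returns (z', logp', grad', accept_stat, divergent)."""
        r0 = self.sqrt_mass * self.rng.standard_normal(z.shape[0])
        joint0 = logp - self._kinetic(r0)
        tree = _Tree(
            z_minus=z, r_minus=r0, grad_minus=grad,
            z_plus=z, r_plus=r0, grad_plus=grad,
            proposal=z, proposal_logp=logp, proposal_grad=grad,
            log_sum_w=0.0, rho=r0.copy(), divergent=False, turning=False,
            sum_accept=0.0, n_leapfrog=0,
        )
        divergent = False
        for depth in range(self.max_treedepth):
            direction = 1 if self.rng.uniform() < 0.5 else -1
            if direction == 1:
                sub = self._build(
                    depth, tree.z_plus, tree.r_plus, tree.grad_plus,
                    step_size, direction, joint0,
                )
            else:
                sub = self._build(
                    depth, tree.z_minus, tree.r_minus, tree.grad_minus,
                    step_size, direction, joint0,
                )
            tree.sum_accept += sub.sum_accept
            tree.n_leapfrog += sub.n_leapfrog
            if sub.divergent:
                divergent = True
                break
            if sub.turning:
                break
            # biased progressive sampling: favour the fresh subtree
            if np.isfinite(sub.log_sum_w):
                if np.log(self.rng.uniform()) < sub.log_sum_w - tree.log_sum_w:
                    tree.proposal = sub.proposal
                    tree.proposal_logp = sub.proposal_logp
                    tree.proposal_grad = sub.proposal_grad
            tree.log_sum_w = np.logaddexp(tree.log_sum_w, sub.log_sum_w)
            tree.rho = tree.rho + sub.rho
            if direction == 1:
                tree.z_plus, tree.r_plus, tree.grad_plus = (
                    sub.z_plus, sub.r_plus, sub.grad_plus,
                )
            else:
                tree.z_minus, tree.r_minus, tree.grad_minus = (
                    sub.z_minus, sub.r_minus, sub.grad_minus,
                )
            if self._turning(tree.rho, tree.r_minus, tree.r_plus):
                break
        accept_stat = tree.sum_accept / max(tree.n_leapfrog, 1)
        return tree.proposal, tree.proposal_logp, tree.proposal_grad, accept_stat, divergent


def _find_initial_step(kernel: _NutsKernel, z, logp, grad) -> float:
    """Heuristic doubling/halving so the first leapfrog step has ~50% accept."""
    step = 1.0
    r0 = kernel.sqrt_mass * kernel.rng.standard_normal(z.shape[0])
    joint0 = logp - kernel._kinetic(r0)
    _, r1, logp1, _ = kernel._leapfrog(z, r0, grad, step)
    joint1 = logp1 - kernel._kinetic(r1)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    for _ in range(50):
        step *= 2.0**direction
        _, r1, logp1, _ = kernel._leapfrog(z, r0, grad, step)
        joint1 = logp1 - kernel._kinetic(r1)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return step


def sample_chain(
    model,
    n_iterations: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    initial: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Run one NUTS chain; returns post-warmup draws (n, dim) and diagnostics."""
    dim = model.dim
    z = model.initial_position(rng) if initial is None else np.asarray(initial, float)
    logp, grad = model.logp_grad(z)
    inv_mass = np.ones(dim)
    kernel = _NutsKernel(model.logp_grad, inv_mass, max_treedepth, rng)

    # dual-averaging state (Hoffman & Gelman)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    def reset_adaptation():
        step0 = _find_initial_step(kernel, z, logp, grad)
        return step0, np.log(10.0 * step0), 0.0, np.log(step0), 0

    step_size, mu, h_bar, log_step_bar, adapt_count = reset_adaptation()

    # mass-matrix estimation window inside warmup
    collect_lo = int(0.25 * warmup)
    collect_hi = int(0.75 * warmup)
    window: list[np.ndarray] = []

    n_keep = n_iterations - warmup
    draws = np.empty((n_keep, dim))
    divergences_post = 0
    divergences_warmup = 0

    for it in range(n_iterations):
        z, logp, grad, accept_stat, divergent = kernel.step(z, logp, grad, step_size)
        if it < warmup:
            if divergent:
                divergences_warmup += 1
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_step = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_step_bar = eta * log_step + (1.0 - eta) * log_step_bar
            step_size = float(np.exp(log_step))
            if collect_lo <= it < collect_hi:
                window.append(z.copy())
            if it == collect_hi - 1 and len(window) >= 10:
                w = np.asarray(window)
                n_w = w.shape[0]
                var = w.var(axis=0, ddof=1)
                # regularize toward unit scale (small-sample shrinkage)
                inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-10)
                kernel.inv_mass = inv_mass
                kernel.sqrt_mass = np.sqrt(1.0 / inv_mass)
                step_size, mu, h_bar, log_step_bar, adapt_count = reset_adaptation()
            if it == warmup - 1:
                step_size = float(np.exp(log_step_bar))
        else:
            if divergent:
                divergences_post += 1
            draws[it - warmup] = z

    info = {
        "step_size": step_size,
        "divergences": divergences_post,
        "divergences_warmup": divergences_warmup,
        "inv_mass": kernel.inv_mass,
    }
    return draws, info


@dataclass
class ModelFit:
    """Posterior draws with chain structure plus sampler diagnostics.

    Every entry of ``draws`` has shape (chains, iterations, k); scalar
    parameters use k = 1.
    """

    draws: dict[str, np.ndarray]
    config: MCMCConfig
    diagnostics: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape[:2] for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError("parameter arrays disagree on chain/iteration shape")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains, shape (chains*iters, k)."""
        v = self.draws[name]
        return v.reshape(-1, v.shape[2])

    @property
    def converged(self) -> bool:
        rh = self.diagnostics.get("rhat", {})
        if not rh:
            return False
        return max(rh.values()) <= self.config.rhat_threshold

    def flat_names(self) -> list[str]:
        names = []
        for key, v in self.draws.items():
            k = v.shape[2]
            names.extend([key] if k == 1 else [f"{key}[{i}]" for i in range(k)])
        return names

    def flat_draws(self, name: str) -> np.ndarray:
        """Pooled draws of one flat parameter like ``beta[3]`` or ``psi``."""
        if "[" in name:
            base, idx = name[:-1].split("[")
            return self.stacked(base)[:, int(idx)]
        return self.stacked(name)[:, 0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format draw table: chain, iteration, parameter, value."""
        frames = []
        for key, v in self.draws.items():
            c, m, k = v.shape
            for i in range(k):
                name = key if k == 1 else f"{key}[{i}]"
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": np.repeat(np.arange(c), m),
                            "iteration": np.tile(np.arange(m), c),
                            "parameter": name,
                            "value": v[:, :, i].reshape(-1),
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def load(cls, path: str | Path) -> "ModelFit":
        """Rebuild a fit from the long-format draw CSV and its sidecar."""
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar_path = path.with_suffix(".diagnostics.json")
        sidecar = (
            json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        )
        chains = int(frame["chain"].max()) + 1
        iters = int(frame["iteration"].max()) + 1
        blocks: dict[str, dict[int, np.ndarray]] = {}
        for name, grp in frame.groupby("parameter", sort=False):
            base, idx = (name[:-1].split("[") + ["0"])[:2] if "[" in name else (name, "0")
            v = np.empty((chains, iters))
            v[grp["chain"].to_numpy(), grp["iteration"].to_numpy()] = grp[
                "value"
            ].to_numpy()
            blocks.setdefault(base, {})[int(idx)] = v
        draws = {
            base: np.stack([cols[i] for i in sorted(cols)], axis=2)
            for base, cols in blocks.items()
        }
        cfg_raw = sidecar.get("config")
        config = MCMCConfig(**cfg_raw) if cfg_raw else MCMCConfig(
            chains=chains, iterations=iters + 1, warmup=1
        )
        return cls(
            draws=draws,
            config=config,
            diagnostics=sidecar.get("diagnostics", {}),
            meta=sidecar.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "config": vars(self.config),
            "diagnostics": {
                k: (v if not isinstance(v, dict) else v)
                for k, v in self.diagnostics.items()
                if k != "inv_mass"
            },
            "meta": self.meta,
        }
        path.with_suffix(".diagnostics.json").write_text(
            json.dumps(sidecar, indent=2, default=float)
        )


def _compute_rhat(draws: dict[str, np.ndarray]) -> dict[str, float]:
    """Max rank-normalized split-Rhat per parameter block (via arviz)."""
    import arviz as az

    out = {}
    for key, v in draws.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.rhat(az.convert_to_dataset(v))
        val = np.asarray(r["x"]).ravel()
        val = val[np.isfinite(val)]
        out[key] = float(val.max()) if val.size else float("nan")
    return out


def fit(model, config: MCMCConfig, compute_diagnostics: bool = True) -> ModelFit:
    """Fit a model by NUTS with the given run settings.

    Chains are run sequentially with independent RNG streams spawned from
    ``config.seed``; output is deterministic for a fixed seed.  A fit is
    flagged non-converged when any parameter's Rhat exceeds the threshold.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.chains)
    chain_draws = []
    chain_info = []
    for c in range(config.chains):
        rng = np.random.default_rng(children[c])
        z, info = sample_chain(
            model,
            n_iterations=config.iterations,
            warmup=config.warmup,
            rng=rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
        )
        if config.thin > 1:
            z = z[:: config.thin]
        chain_draws.append(z)
        chain_info.append(info)

    constrained: dict[str, list[np.ndarray]] = {}
    for z in chain_draws:
        named = model.constrain_batch(z)
        for key, v in named.items():
            constrained.setdefault(key, []).append(v)
    draws = {key: np.stack(v, axis=0) for key, v in constrained.items()}

    diagnostics: dict = {
        "divergences": [info["divergences"] for info in chain_info],
        "divergences_warmup": [info["divergences_warmup"] for info in chain_info],
        "step_sizes": [info["step_size"] for info in chain_info],
    }
    if compute_diagnostics:
        diagnostics["rhat"] = _compute_rhat(draws)
        if max(diagnostics["rhat"].values()) > config.rhat_threshold:
            warnings.warn(
                f"fit flagged non-converged: max Rhat = "
                f"{max(diagnostics['rhat'].values()):.4f}"
            )
    total_div = sum(diagnostics["divergences"])
    if total_div:
        warnings.warn(f"{total_div} post-warmup divergences reported")
    return ModelFit(draws=draws, config=config, diagnostics=diagnostics)


def thin(fit: ModelFit, rate: float) -> ModelFit:
    """Keep every k-th draw.  ``rate`` may be a fraction (1/2 keeps every
    second draw) or an integer stride (2 means the same)."""
    if rate <= 0:
        raise ValueError("thinning rate must be positive")
    stride = int(round(1.0 / rate)) if rate < 1 else int(round(rate))
    if stride == 1:
        return fit
    draws = {k: v[:, ::stride] for k, v in fit.draws.items()}
    return ModelFit(
        draws=draws,
        config=fit.config,
        diagnostics={**fit.diagnostics, "thinned_by": stride},
        meta=dict(fit.meta),
    )
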
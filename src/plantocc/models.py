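"""Two-part binomial (TPB) likelihood and the hierarchical Models 1 and 2.

The TPB likelihood treats "did the study report the occurrence count" as a
Bernoulli(psi) event: an unreported record contributes log(1 - psi); a
reported record contributes log(psi) plus a Binomial(y | N, p_i) term with
p_i modeled on the logit scale.

Model 1:  logit(p_i) = alpha_j + tau_i,          tau_i ~ Normal(0, theta_j^2)
Model 2:  logit(p_i) = alpha_j + X_env_i . beta + tau_i
          alpha_j    = I + X_sp_j . eps + phi_j,  phi_j ~ Normal(0, omega^2)

Priors: intercepts and coefficients ~ Student-t(3, 0, 5); scale
hyperparameters (omega, theta_j) ~ Exponential(1); psi ~ Uniform(0, 1).

Each model exposes the joint log posterior density and its gradient over an
unconstrained parameter vector (log-transformed scales, logit-transformed
psi, non-centered tau and phi), which is what the NUTS sampler consumes.
The non-centering and transforms change only the geometry, not the density
over the original parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from plantocc.data import DietRecord, ENV_COLUMNS

try:  # fused gradient kernels; the numpy path below is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap

__all__ = [
    "MCMCConfig",
    "TPBData",
    "tpb_loglik",
    "Model1",
    "Model2",
    "PsiOnlyModel",
    "build_model1",
    "build_model2",
]

# log normalizing constant of Student-t(nu=3, mu=0, sigma=5)
_T_NU, _T_SIGMA = 3.0, 5.0
_T_CONST = float(
    gammaln((_T_NU + 1) / 2)
    - gammaln(_T_NU / 2)
    - 0.5 * np.log(_T_NU * np.pi)
    - np.log(_T_SIGMA)
)
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
_T_KCONST = _T_CONST


def _t_logpdf(x: np.ndarray) -> np.ndarray:
    return _T_CONST - ((_T_NU + 1) / 2) * np.log1p(x**2 / (_T_NU * _T_SIGMA**2))


def _t_grad(x: np.ndarray) -> np.ndarray:
    return -(_T_NU + 1) * x / (_T_NU * _T_SIGMA**2 + x**2)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@_njit(cache=True)
def _m1_kernel(z, sp, N, y_rep, rep, J, n, include_psi, log_binom_const):
    alpha = z[:J]
    lt = z[J : 2 * J]
    z_tau = z[2 * J : 2 * J + n]
    grad = np.zeros(z.shape[0])
    theta = np.exp(lt)
    logp = log_binom_const
    half_log_2pi = 0.9189385332046727
    for j in range(J):
        a = alpha[j]
        logp += _T_KCONST - 2.0 * np.log1p(a * a / 75.0)
        grad[j] += -4.0 * a / (75.0 + a * a)
        logp += -theta[j] + lt[j]
        grad[J + j] += 1.0 - theta[j]
    for i in range(n):
        j = sp[i]
        zt = z_tau[i]
        logp += -0.5 * zt * zt - half_log_2pi
        eta = alpha[j] + theta[j] * zt
        g = 0.0
        if rep[i]:
            if eta > 0.0:
                sp_eta = eta + np.log1p(np.exp(-eta))
            else:
                sp_eta = np.log1p(np.exp(eta))
            logp += y_rep[i] * eta - N[i] * sp_eta
            g = y_rep[i] - N[i] / (1.0 + np.exp(-eta))
            grad[j] += g
            grad[J + j] += theta[j] * g * zt
        grad[2 * J + i] = theta[j] * g - zt
    if include_psi:
        u = z[2 * J + n]
        psi = 1.0 / (1.0 + np.exp(-u))
        a = 0.0
        b = 0.0
        for i in range(n):
            if rep[i]:
                a += 1.0
            else:
                b += 1.0
        a += 1.0
        b += 1.0
        if u > 0.0:
            log_psi = -np.log1p(np.exp(-u))
            log_1mpsi = -u - np.log1p(np.exp(-u))
        else:
            log_psi = u - np.log1p(np.exp(u))
            log_1mpsi = -np.log1p(np.exp(u))
        logp += a * log_psi + b * log_1mpsi
        grad[2 * J + n] = a * (1.0 - psi) - b * psi
    return logp, grad


@_njit(cache=True)
def _m2_kernel(z, sp, N, y_rep, rep, X_env, X_sp, J, n, s, t,
               include_psi, log_binom_const):
    pos = 0
    intercept = z[pos]; pos += 1
    beta = z[pos : pos + s]; pos += s
    eps = z[pos : pos + t]; pos += t
    lo = z[pos]; pos += 1
    z_phi = z[pos : pos + J]; pos += J
    lt = z[pos : pos + J]; pos += J
    z_tau = z[pos : pos + n]
    grad = np.zeros(z.shape[0])
    omega = np.exp(lo)
    theta = np.exp(lt)
    half_log_2pi = 0.9189385332046727
    logp = log_binom_const

    logp += _T_KCONST - 2.0 * np.log1p(intercept * intercept / 75.0)
    grad[0] += -4.0 * intercept / (75.0 + intercept * intercept)
    for k in range(s):
        bk = beta[k]
        logp += _T_KCONST - 2.0 * np.log1p(bk * bk / 75.0)
        grad[1 + k] += -4.0 * bk / (75.0 + bk * bk)
    for k in range(t):
        ek = eps[k]
        logp += _T_KCONST - 2.0 * np.log1p(ek * ek / 75.0)
        grad[1 + s + k] += -4.0 * ek / (75.0 + ek * ek)
    logp += -omega + lo
    grad[1 + s + t] += 1.0 - omega

    alpha = np.empty(J)
    for j in range(J):
        a = intercept + omega * z_phi[j]
        for k in range(t):
            a += X_sp[j, k] * eps[k]
        alpha[j] = a
        zp = z_phi[j]
        logp += -0.5 * zp * zp - half_log_2pi
        grad[2 + s + t + j] += -zp
        logp += -theta[j] + lt[j]
        grad[2 + s + t + J + j] += 1.0 - theta[j]

    off_zphi = 2 + s + t
    off_lt = off_zphi + J
    off_ztau = off_lt + J
    gs = np.zeros(J)
    for i in range(n):
        j = sp[i]
        zt = z_tau[i]
        logp += -0.5 * zt * zt - half_log_2pi
        eta = alpha[j] + theta[j] * zt
        for k in range(s):
            eta += X_env[i, k] * beta[k]
        g = 0.0
        if rep[i]:
            if eta > 0.0:
                sp_eta = eta + np.log1p(np.exp(-eta))
            else:
                sp_eta = np.log1p(np.exp(eta))
            logp += y_rep[i] * eta - N[i] * sp_eta
            g = y_rep[i] - N[i] / (1.0 + np.exp(-eta))
            gs[j] += g
            for k in range(s):
                grad[1 + k] += X_env[i, k] * g
            grad[off_lt + j] += theta[j] * g * zt
        grad[off_ztau + i] = theta[j] * g - zt
    gs_total = 0.0
    rho = 0.0
    for j in range(J):
        gs_total += gs[j]
        rho += z_phi[j] * gs[j]
        grad[off_zphi + j] += omega * gs[j]
        for k in range(t):
            grad[1 + s + k] += X_sp[j, k] * gs[j]
    grad[0] += gs_total
    grad[1 + s + t] += omega * rho

    if include_psi:
        u = z[off_ztau + n]
        psi = 1.0 / (1.0 + np.exp(-u))
        a = 1.0
        b = 1.0
        for i in range(n):
            if rep[i]:
                a += 1.0
            else:
                b += 1.0
        if u > 0.0:
            log_psi = -np.log1p(np.exp(-u))
            log_1mpsi = -u - np.log1p(np.exp(-u))
        else:
            log_psi = u - np.log1p(np.exp(u))
            log_1mpsi = -np.log1p(np.exp(u))
        logp += a * log_psi + b * log_1mpsi
        grad[off_ztau + n] = a * (1.0 - psi) - b * psi
    return logp, grad


@dataclass
class MCMCConfig:
    """NUTS run settings.

    Defaults follow the headline analysis: four chains, 5,000 iterations with
    2,000 warm-ups for non-imputed fits.  Imputed replicate fits use
    2,000/1,500 (see :func:`plantocc.imputation.replicate_fit_and_pool`).
    """

    chains: int = 4
    iterations: int = 5000
    warmup: int = 2000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.01
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class TPBData:
    """Validated record-level arrays shared by both models.

    Species are indexed 0..J-1 in the order of ``species_labels``; species
    with no records are dropped at construction (with a warning) since they
    are unidentifiable.
    """

    species_labels: list[str]
    species_idx: np.ndarray  # (n,) int
    N: np.ndarray  # (n,) int
    y: np.ndarray  # (n,) float, nan when unreported
    reported: np.ndarray  # (n,) bool
    X_env: np.ndarray | None = None  # (n, s)
    X_sp: np.ndarray | None = None  # (J, t)
    env_names: list[str] = field(default_factory=list)
    sp_names: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.N)

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    @classmethod
    def from_records(
        cls,
        records: list[DietRecord],
        X_env: np.ndarray | None = None,
        X_sp: np.ndarray | None = None,
        species_labels: list[str] | None = None,
        env_names: list[str] | None = None,
        sp_names: list[str] | None = None,
    ) -> "TPBData":
        for i, rec in enumerate(records):
            rec.validate(row=i)
        present = sorted({r.species_id for r in records})
        if species_labels is None:
            species_labels = present
        else:
            absent = [s for s in species_labels if s not in present]
            if absent:
                warnings.warn(
                    f"species with zero records excluded from the fit: {absent}"
                )
            keep = [s for s in species_labels if s in present]
            if X_sp is not None:
                rows = [species_labels.index(s) for s in keep]
                X_sp = np.asarray(X_sp)[rows]
            species_labels = keep
        unknown = {r.species_id for r in records} - set(species_labels)
        if unknown:
            raise ValueError(f"records reference species not in the design: {sorted(unknown)}")
        index = {s: j for j, s in enumerate(species_labels)}
        sp = np.array([index[r.species_id] for r in records], dtype=np.int64)
        N = np.array([r.N for r in records], dtype=np.int64)
        y = np.array([np.nan if r.y is None else float(r.y) for r in records])
        reported = ~np.isnan(y)
        if X_env is not None:
            X_env = np.asarray(X_env, dtype=float)
            if X_env.shape[0] != len(records):
                raise ValueError("X_env row count does not match record count")
        if X_sp is not None:
            X_sp = np.asarray(X_sp, dtype=float)
            if X_sp.shape[0] != len(species_labels):
                raise ValueError("X_sp row count does not match species count")
        return cls(
            species_labels=species_labels,
            species_idx=sp,
            N=N,
            y=y,
            reported=reported,
            X_env=X_env,
            X_sp=X_sp,
            env_names=list(env_names or []),
            sp_names=list(sp_names or []),
        )


def tpb_loglik(record: DietRecord, psi: float, p: float) -> float:
    """Log-likelihood contribution of one record under the TPB model.

    Unreported: log(1 - psi), independent of p.  Reported: log(psi) plus the
    binomial log-pmf of y successes in N trials at rate p.
    """
    if not 0.0 < psi < 1.0:
        raise ValueError("psi must lie strictly in (0, 1)")
    if record.y is None:
        return float(np.log1p(-psi))
    y, n = record.y, record.N
    if p <= 0.0 or p >= 1.0:
        # boundary p is admissible only when y sits at the matching boundary
        if (p <= 0.0 and y == 0) or (p >= 1.0 and y == n):
            return float(np.log(psi))
        raise ValueError("p outside (0,1) with a non-matching count")
    logbinom = (
        gammaln(n + 1)
        - gammaln(y + 1)
        - gammaln(n - y + 1)
        + y * np.log(p)
        + (n - y) * np.log1p(-p)
    )
    return float(np.log(psi) + logbinom)


class _TPBModel:
    """Shared machinery: binomial likelihood on the logit scale, psi block.

    Subclasses define the parameter layout and the linear predictor.
    """

    data: TPBData
    include_psi: bool

    def __init__(self, data: TPBData, include_psi: bool = True) -> None:
        self.data = data
        self.include_psi = include_psi
        d = data
        self._rep = d.reported
        self._y_rep = np.where(d.reported, np.nan_to_num(d.y), 0.0)
        self._n_rep = int(d.reported.sum())
        self._n_unrep = int((~d.reported).sum())
        # binomial coefficients are constants of the data
        yr = self._y_rep[self._rep]
        nr = d.N[self._rep].astype(float)
        self._log_binom_const = float(
            np.sum(gammaln(nr + 1) - gammaln(yr + 1) - gammaln(nr - yr + 1))
        )
        self._Nf = d.N.astype(np.float64)

    # -- psi block ---------------------------------------------------------
    def _psi_logp_grad(self, u: float) -> tuple[float, float]:
        """Uniform(0,1) prior + logit Jacobian + Bernoulli reporting terms."""
        psi = expit(u)
        a = self._n_rep + 1.0  # +1 from the Jacobian log(psi)
        b = self._n_unrep + 1.0  # +1 from the Jacobian log(1-psi)
        logp = -a * _softplus(-u) - b * _softplus(u)  # stable log psi, log(1-psi)
        grad = a * (1.0 - psi) - b * psi
        return float(logp), float(grad)

    # -- binomial block ----------------------------------------------------
    def _binom_logp(self, eta: np.ndarray) -> float:
        """Sum over reported records of the binomial log-pmf at logit eta."""
        r = self._rep
        ll = self._y_rep[r] * eta[r] - self.data.N[r] * _softplus(eta[r])
        return float(ll.sum()) + self._log_binom_const

    def _binom_grad_eta(self, eta: np.ndarray) -> np.ndarray:
        """d loglik / d eta per record; zero for unreported records."""
        g = self._y_rep - self.data.N * expit(eta)
        return np.where(self._rep, g, 0.0)

    # -- interface for the sampler ----------------------------------------
    @property
    def dim(self) -> int:
        raise NotImplementedError

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def constrain_batch(self, Z: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        return 0.1 * rng.standard_normal(self.dim)


class Model1(_TPBModel):
    """Per-species frequency model: logit(p_i) = alpha_j + tau_i.

    Unconstrained layout: [alpha (J), log theta (J), z_tau (n), logit psi].
    tau_i = theta_{j(i)} * z_tau_i (non-centered).
    """

    @property
    def dim(self) -> int:
        d = self.data
        return 2 * d.n_species + d.n_records + (1 if self.include_psi else 0)

    def _split(self, z: np.ndarray):
        j, n = self.data.n_species, self.data.n_records
        alpha = z[:j]
        lt = z[j : 2 * j]
        z_tau = z[2 * j : 2 * j + n]
        u = z[-1] if self.include_psi else None
        return alpha, lt, z_tau, u

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        if _HAVE_NUMBA:
            d = self.data
            return _m1_kernel(
                z, d.species_idx, self._Nf, self._y_rep, self._rep,
                d.n_species, d.n_records, self.include_psi,
                self._log_binom_const,
            )
        return self._logp_grad_numpy(z)

    def _logp_grad_numpy(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.data
        sp = d.species_idx
        alpha, lt, z_tau, u = self._split(z)
        theta = np.exp(lt)
        eta = alpha[sp] + theta[sp] * z_tau

        logp = self._binom_logp(eta)
        logp += float(np.sum(_t_logpdf(alpha)))
        logp += float(np.sum(-theta + lt))  # Exp(1) prior + log Jacobian
        logp += float(np.sum(-0.5 * z_tau**2 - _HALF_LOG_2PI))

        g_eta = self._binom_grad_eta(eta)
        gs = np.bincount(sp, weights=g_eta, minlength=d.n_species)
        g_alpha = gs + _t_grad(alpha)
        g_lt = theta * np.bincount(sp, weights=g_eta * z_tau, minlength=d.n_species)
        g_lt += 1.0 - theta
        g_ztau = theta[sp] * g_eta - z_tau

        grad = np.concatenate([g_alpha, g_lt, g_ztau])
        if self.include_psi:
            lp_psi, g_u = self._psi_logp_grad(float(u))
            logp += lp_psi
            grad = np.append(grad, g_u)
        return logp, grad

    def constrain_batch(self, Z: np.ndarray) -> dict[str, np.ndarray]:
        d = self.data
        j, n = d.n_species, d.n_records
        alpha = Z[:, :j]
        theta = np.exp(Z[:, j : 2 * j])
        z_tau = Z[:, 2 * j : 2 * j + n]
        tau = theta[:, d.species_idx] * z_tau
        eta = alpha[:, d.species_idx] + tau
        out = {
            "alpha": alpha,
            "theta": theta,
            "tau": tau,
            "p": expit(eta),
            "freq": expit(alpha),
        }
        if self.include_psi:
            out["psi"] = expit(Z[:, -1:])
        return out


class Model2(_TPBModel):
    """Covariate model: logit(p_i) = alpha_j + X_env_i . beta + tau_i with
    alpha_j = I + X_sp_j . eps + phi_j.

    Unconstrained layout:
    [I, beta (s), eps (t), log omega, z_phi (J), log theta (J), z_tau (n),
    logit psi].  phi_j = omega * z_phi_j and tau_i = theta_{j(i)} * z_tau_i.
    """

    def __init__(self, data: TPBData, include_psi: bool = True) -> None:
        if data.X_env is None or data.X_sp is None:
            raise ValueError("Model 2 requires X_env and X_sp design matrices")
        super().__init__(data, include_psi)
        self.s = data.X_env.shape[1]
        self.t = data.X_sp.shape[1]

    @property
    def dim(self) -> int:
        d = self.data
        return (
            1 + self.s + self.t + 1 + 2 * d.n_species + d.n_records
            + (1 if self.include_psi else 0)
        )

    def _split(self, z: np.ndarray):
        j, n = self.data.n_species, self.data.n_records
        s, t = self.s, self.t
        pos = 0
        intercept = z[pos]; pos += 1
        beta = z[pos : pos + s]; pos += s
        eps = z[pos : pos + t]; pos += t
        lo = z[pos]; pos += 1
        z_phi = z[pos : pos + j]; pos += j
        lt = z[pos : pos + j]; pos += j
        z_tau = z[pos : pos + n]; pos += n
        u = z[pos] if self.include_psi else None
        return intercept, beta, eps, lo, z_phi, lt, z_tau, u

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        if _HAVE_NUMBA:
            d = self.data
            return _m2_kernel(
                z, d.species_idx, self._Nf, self._y_rep, self._rep,
                d.X_env, d.X_sp, d.n_species, d.n_records, self.s, self.t,
                self.include_psi, self._log_binom_const,
            )
        return self._logp_grad_numpy(z)

    def _logp_grad_numpy(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.data
        sp = d.species_idx
        intercept, beta, eps, lo, z_phi, lt, z_tau, u = self._split(z)
        omega = np.exp(lo)
        theta = np.exp(lt)
        alpha = intercept + d.X_sp @ eps + omega * z_phi
        eta = alpha[sp] + d.X_env @ beta + theta[sp] * z_tau

        logp = self._binom_logp(eta)
        logp += float(_t_logpdf(np.atleast_1d(intercept)).sum())
        logp += float(np.sum(_t_logpdf(beta)) + np.sum(_t_logpdf(eps)))
        logp += float(-omega + lo)
        logp += float(np.sum(-theta + lt))
        logp += float(np.sum(-0.5 * z_phi**2 - _HALF_LOG_2PI))
        logp += float(np.sum(-0.5 * z_tau**2 - _HALF_LOG_2PI))

        g_eta = self._binom_grad_eta(eta)
        gs = np.bincount(sp, weights=g_eta, minlength=d.n_species)
        g_I = float(gs.sum()) + float(_t_grad(np.atleast_1d(intercept))[0])
        g_beta = d.X_env.T @ g_eta + _t_grad(beta)
        g_eps = d.X_sp.T @ gs + _t_grad(eps)
        g_zphi = omega * gs - z_phi
        g_lo = float(omega * (z_phi @ gs)) + 1.0 - float(omega)
        g_lt = theta * np.bincount(sp, weights=g_eta * z_tau, minlength=d.n_species)
        g_lt += 1.0 - theta
        g_ztau = theta[sp] * g_eta - z_tau

        grad = np.concatenate(
            [[g_I], g_beta, g_eps, [g_lo], g_zphi, g_lt, g_ztau]
        )
        if self.include_psi:
            lp_psi, g_u = self._psi_logp_grad(float(u))
            logp += lp_psi
            grad = np.append(grad, g_u)
        return logp, grad

    def constrain_batch(self, Z: np.ndarray) -> dict[str, np.ndarray]:
        d = self.data
        j, n, s, t = d.n_species, d.n_records, self.s, self.t
        pos = 0
        intercept = Z[:, pos : pos + 1]; pos += 1
        beta = Z[:, pos : pos + s]; pos += s
        eps = Z[:, pos : pos + t]; pos += t
        omega = np.exp(Z[:, pos : pos + 1]); pos += 1
        z_phi = Z[:, pos : pos + j]; pos += j
        theta = np.exp(Z[:, pos : pos + j]); pos += j
        z_tau = Z[:, pos : pos + n]; pos += n
        phi = omega * z_phi
        alpha = intercept + (d.X_sp @ eps.T).T + phi
        tau = theta[:, d.species_idx] * z_tau
        eta = alpha[:, d.species_idx] + (d.X_env @ beta.T).T + tau
        out = {
            "I": intercept,
            "beta": beta,
            "eps": eps,
            "omega": omega,
            "phi": phi,
            "alpha": alpha,
            "theta": theta,
            "tau": tau,
            "p": expit(eta),
            "freq": expit(alpha),
        }
        if self.include_psi:
            out["psi"] = expit(Z[:, pos : pos + 1])
        return out


class PsiOnlyModel:
    """Reduced model in which only the reporting probability is estimated.

    With a Uniform(0,1) prior the posterior is Beta(1 + R, 1 + M - R) in
    closed form, which makes this model the conjugate calibration check for
    the sampler.
    """

    def __init__(self, n_reported: int, n_unreported: int) -> None:
        self.n_reported = n_reported
        self.n_unreported = n_unreported

    @property
    def dim(self) -> int:
        return 1

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        u = float(z[0])
        psi = expit(u)
        a = self.n_reported + 1.0
        b = self.n_unreported + 1.0
        logp = -a * _softplus(-u) - b * _softplus(u)
        grad = np.array([a * (1.0 - psi) - b * psi])
        return float(logp), grad

    def constrain_batch(self, Z: np.ndarray) -> dict[str, np.ndarray]:
        return {"psi": expit(Z[:, :1])}

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        return 0.1 * rng.standard_normal(1)


def build_model1(
    records: list[DietRecord],
    include_psi: bool = True,
    species_labels: list[str] | None = None,
) -> Model1:
    """Joint log-density of Model 1 over validated records."""
    data = TPBData.from_records(records, species_labels=species_labels)
    return Model1(data, include_psi=include_psi)


def build_model2(
    records: list[DietRecord],
    X_env: np.ndarray,
    X_sp: np.ndarray,
    species_labels: list[str],
    include_psi: bool = True,
    env_names: list[str] | None = None,
    sp_names: list[str] | None = None,
) -> Model2:
    """Joint log-density of Model 2; designs must align with species_labels."""
    data = TPBData.from_records(
        records,
        X_env=X_env,
        X_sp=X_sp,
        species_labels=species_labels,
        env_names=env_names or list(ENV_COLUMNS),
        sp_names=sp_names,
    )
    return Model2(data, include_psi=include_psi)
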
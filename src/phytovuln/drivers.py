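"""Which climate changes drive relative vulnerability?

Per-pixel relative vulnerability (a proportion in [0, 1]) is regressed on
per-variable climate change (future minus present) with beta regression
(logit mean link).  Importance is assessed by resampled all-subsets model
selection: each iteration draws 500 random pixels, fits every non-empty
variable subset (plus the intercept-only model), and computes Akaike
weights ``w_m = exp(-dAIC_m / 2) / sum(...)``.  A variable's importance is
(1) *wg*, the per-iteration summed weight of models containing it averaged
over iterations, and (2) *N*, the number of iterations whose AIC-best model
contains it.  Coefficients are model-averaged conditionally on inclusion,
with unconditional standard errors.

Localities can be modeled with a random intercept (Laplace-approximated
maximum likelihood, see :func:`fit_beta_glmm`); when every locality is a
singleton pixel — as in the 500-random-pixel iterations — the random
intercept is unidentifiable and the fixed-effects beta regression is used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.othermod.betareg import BetaModel

from .grids import ClimateGrid
from .synthetic import EcoregionMap
from .vulnerability import VulnerabilityMap


def shrink_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Compress proportions off the boundary: y' = (y (n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    n = y.size if n is None else n
    return (y * (n - 1) + 0.5) / n


def build_driver_dataset(
    vuln: VulnerabilityMap,
    climate_present: ClimateGrid,
    climate_future: ClimateGrid,
    ecoregions: EcoregionMap | None = None,
) -> pd.DataFrame:
    """One record per occupied pixel: response, per-variable deltas, locality.

    Deltas are future minus present.  Locality defaults to the pixel itself
    (``px<row>_<col>``); with an ecoregion map, pixels are grouped by region.
    """
    if climate_present.spec.shape != climate_future.spec.shape:
        raise ValueError("present and future grids are misaligned")
    if vuln.richness.shape != climate_present.spec.shape:
        raise ValueError("vulnerability map misaligned with climate grids")
    rows, cols = np.nonzero(vuln.richness > 0)
    out = pd.DataFrame({
        "row": rows,
        "col": cols,
        "relative_vulnerability": vuln.relative_vulnerability[rows, cols],
    })
    for v in climate_present.variables:
        out[f"d_{v}"] = climate_future.values[v][rows, cols] - climate_present.values[v][rows, cols]
    if ecoregions is not None:
        out["locality"] = [ecoregions.names[r] for r in ecoregions.region_id[rows, cols]]
    else:
        out["locality"] = [f"px{r}_{c}" for r, c in zip(rows, cols)]
    return out


@dataclass
class BetaFit:
    """One fitted beta regression (fixed or random intercept)."""

    variables: tuple[str, ...]
    params: pd.Series            # mean-model coefficients incl. const
    bse: pd.Series
    loglik: float
    aic: float
    converged: bool
    phi: float
    sigma_u: float = 0.0         # random-intercept SD (0 for fixed effects)

    @property
    def k(self) -> int:
        # mean coefficients + dispersion (+ random-intercept SD if present)
        return len(self.params) + 1 + (1 if self.sigma_u > 0 else 0)


def _design(records: pd.DataFrame, variables: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = shrink_unit_interval(records["relative_vulnerability"].to_numpy())
    names = ["const", *variables]
    X = np.column_stack([np.ones(len(records))] +
                        [records[v].to_numpy(dtype=float) for v in variables])
    return y, X, names


def _fit_beta_fixed(records: pd.DataFrame, variables: tuple[str, ...]) -> BetaFit:
    y, X, names = _design(records, variables)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BetaModel(y, X).fit(disp=False, maxiter=500)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        # give the default optimizer's endpoint a Newton polish before
        # declaring failure
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res2 = BetaModel(y, X).fit(disp=False, method="newton",
                                           start_params=res.params, maxiter=100)
                if res2.mle_retvals.get("converged", False):
                    res, converged = res2, True
            except Exception:
                pass
    params = pd.Series(res.params[:-1], index=names)
    bse = pd.Series(res.bse[:-1], index=names)
    llf = float(res.llf)
    k = len(res.params)
    return BetaFit(
        variables=variables, params=params, bse=bse, loglik=llf,
        aic=2.0 * k - 2.0 * llf, converged=converged,
        phi=float(np.exp(res.params[-1])),
    )


def _beta_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    a = mu * phi
    b = (1.0 - mu) * phi
    return ((a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
            + special.gammaln(phi) - special.gammaln(a) - special.gammaln(b))


def _fit_beta_random(records: pd.DataFrame, variables: tuple[str, ...],
                     locality: str = "locality") -> BetaFit:
    """Random-intercept beta regression via a Laplace approximation.

    The marginal likelihood integrates a Gaussian locality intercept out of
    the beta likelihood; each group's integral is approximated at its mode
    (found by 1-D Newton steps).  Suitable for modest group counts.
    """
    y, X, names = _design(records, variables)
    groups = records[locality].to_numpy()
    uniq, gidx = np.unique(groups, return_inverse=True)
    n_groups = uniq.size
    if n_groups == len(records):
        raise ValueError("every locality is a singleton: random intercept unidentifiable; "
                         "use the fixed-effects fit")

    start = _fit_beta_fixed(records, variables)
    theta0 = np.concatenate([start.params.to_numpy(), [np.log(start.phi)], [np.log(0.25)]])

    def group_mode(eta_g, y_g, phi, sigma2):
        u = 0.0
        for _ in range(30):
            mu = special.expit(eta_g + u)
            a, b = mu * phi, (1 - mu) * phi
            # d/du log f = sum phi * mu(1-mu) * (log(y/(1-y)) - psi(a) + psi(b)) - u/sigma2
            w = phi * mu * (1 - mu)
            r = np.log(y_g / (1 - y_g)) - special.digamma(a) + special.digamma(b)
            grad = np.sum(w * r) - u / sigma2
            dw = phi * mu * (1 - mu) * (1 - 2 * mu)
            dr = -phi * mu * (1 - mu) * (special.polygamma(1, a) + special.polygamma(1, b))
            hess = np.sum(dw * r + w * dr) - 1.0 / sigma2
            if hess >= 0:
                hess = -1.0 / sigma2
            step = grad / hess
            u -= step
            if abs(step) < 1e-10:
                break
        return u, hess

    def negloglik(theta):
        beta = theta[:-2]
        phi = np.exp(theta[-2])
        sigma2 = np.exp(2 * theta[-1])
        eta = X @ beta
        ll = 0.0
        for g in range(n_groups):
            sel = gidx == g
            u_hat, hess = group_mode(eta[sel], y[sel], phi, sigma2)
            mu = np.clip(special.expit(eta[sel] + u_hat), 1e-10, 1 - 1e-10)
            lg = (_beta_loglik(y[sel], mu, phi).sum()
                  - 0.5 * np.log(2 * np.pi * sigma2) - 0.5 * u_hat**2 / sigma2)
            ll += lg + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(-hess)
        return -ll

    res = optimize.minimize(negloglik, theta0, method="BFGS",
                            options={"maxiter": 200, "gtol": 1e-5})
    theta = res.x
    # BFGS with numerical gradients often stops on precision loss at the
    # optimum; accept if the remaining gradient is negligible
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3 * (1.0 + abs(res.fun))
    # standard errors from the numerical inverse Hessian of the optimizer
    bse_all = np.sqrt(np.maximum(np.diag(res.hess_inv), 0.0))
    llf = -float(res.fun)
    k = theta.size
    return BetaFit(
        variables=variables,
        params=pd.Series(theta[:-2], index=names),
        bse=pd.Series(bse_all[:-2], index=names),
        loglik=llf, aic=2.0 * k - 2.0 * llf, converged=bool(res.success or grad_ok),
        phi=float(np.exp(theta[-2])), sigma_u=float(np.exp(theta[-1])),
    )


def fit_beta_glmm(
    records: pd.DataFrame,
    variables: tuple[str, ...] | list[str],
    random_intercept: bool | None = None,
    locality: str = "locality",
) -> BetaFit:
    """Beta regression of relative vulnerability on climate deltas.

    With ``random_intercept=None`` (auto) a locality random intercept is
    used when localities group multiple pixels and dropped (fixed-effects
    fit) when every locality is a singleton.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    variables = tuple(variables)
    if random_intercept is None:
        random_intercept = (locality in records.columns
                            and records[locality].nunique() < len(records))
    if random_intercept:
        return _fit_beta_random(records, variables, locality=locality)
    return _fit_beta_fixed(records, variables)


# ---------------------------------------------------------------------------
# resampled all-subsets importance

def all_subsets(variables: tuple[str, ...]) -> list[tuple[str, ...]]:
    """Every variable subset as a candidate model, including the
    intercept-only model (empty tuple)."""
    subsets: list[tuple[str, ...]] = []
    for r in range(len(variables) + 1):
        subsets.extend(itertools.combinations(variables, r))
    return subsets


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """exp(-dAIC/2), normalized to sum to one."""
    d = np.asarray(aics, dtype=float) - np.min(aics)
    w = np.exp(-d / 2.0)
    return w / w.sum()


class DriverImportanceModel:
    """Resampled all-subsets beta-regression importance analysis.

    Parameters
    ----------
    dataset
        Output of :func:`build_driver_dataset` (or any frame with a
        ``relative_vulnerability`` column and the candidate predictors).
    variables
        Candidate predictors; default: every ``d_*`` column.
    """

    def __init__(self, dataset: pd.DataFrame, variables: list[str] | None = None):
        self.dataset = dataset.reset_index(drop=True)
        if variables is None:
            variables = [c for c in dataset.columns if c.startswith("d_")]
        if not variables:
            raise ValueError("no candidate variables")
        self.variables = tuple(variables)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "relative_vulnerability",
                       variables: list[str] | None = None) -> "DriverImportanceModel":
        out = df.rename(columns={response: "relative_vulnerability"})
        return cls(out, variables=variables)

    def fit(
        self,
        n_iter: int = 1000,
        n_points: int = 500,
        seed: int | np.random.SeedSequence = 0,
        wg_mode: str = "summed",
        max_resample: int = 3,
    ) -> "DriverImportanceResults":
        """Run the iteration loop and aggregate importance.

        wg_mode="summed" (default) averages each variable's per-iteration
        summed Akaike weight over models containing it; "best" averages the
        best model's weight over the iterations where that best model
        contains the variable.
        """
        if len(self.dataset) < n_points:
            raise ValueError(f"dataset has {len(self.dataset)} records < n_points={n_points}")
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss)
        subsets = all_subsets(self.variables)
        contains = {v: np.array([v in s for s in subsets]) for v in self.variables}

        wg_sum = {v: 0.0 for v in self.variables}
        wg_n = {v: 0 for v in self.variables}
        best_count = {v: 0 for v in self.variables}
        coef_acc: dict[str, list[tuple[float, float]]] = {v: [] for v in self.variables}
        iter_log = []
        n_done = 0
        n_skipped = 0
        for it in range(n_iter):
            fits = None
            for attempt in range(max_resample):
                idx = rng.choice(len(self.dataset), size=n_points, replace=False)
                sample = self.dataset.iloc[idx]
                try:
                    cand = [_fit_beta_fixed(sample, s) for s in subsets]
                except Exception:
                    continue
                if all(f.converged for f in cand):
                    fits = cand
                    break
            if fits is None:
                n_skipped += 1
                continue
            n_done += 1
            aics = np.array([f.aic for f in fits])
            w = akaike_weights(aics)
            best = int(np.argmin(aics))
            for v in self.variables:
                mask = contains[v]
                if wg_mode == "summed":
                    wg_sum[v] += float(w[mask].sum())
                    wg_n[v] += 1
                elif wg_mode == "best":
                    if mask[best]:
                        wg_sum[v] += float(w[best])
                        wg_n[v] += 1
                else:
                    raise ValueError(f"unknown wg_mode {wg_mode!r}")
                if mask[best]:
                    best_count[v] += 1
                # conditional model-averaged coefficient for this iteration
                wv = w[mask]
                if wv.sum() > 0:
                    betas = np.array([fits[i].params[v] for i in np.nonzero(mask)[0]])
                    ses = np.array([fits[i].bse[v] for i in np.nonzero(mask)[0]])
                    wt = wv / wv.sum()
                    bbar = float(wt @ betas)
                    se_u = float(np.sqrt(wt @ (ses**2 + (betas - bbar) ** 2)))
                    coef_acc[v].append((bbar, se_u))
            iter_log.append({
                "iteration": it, "best_model": "+".join(subsets[best]) or "(intercept)",
                "best_aic": float(aics[best]), "best_weight": float(w[best]),
            })

        if n_done == 0:
            raise RuntimeError("no iteration produced a converged model set")
        imp_rows = []
        for v in self.variables:
            wg = wg_sum[v] / wg_n[v] if wg_n[v] else 0.0
            coefs = np.array([c for c, _ in coef_acc[v]])
            ses = np.array([s for _, s in coef_acc[v]])
            # occasional fits yield a singular Hessian (NaN SE); average over the rest
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coef = float(np.nanmean(coefs)) if coefs.size else np.nan
                se = float(np.nanmean(ses)) if ses.size else np.nan
            z = abs(coef) / se if se and np.isfinite(se) and se > 0 else np.nan
            p = 2.0 * stats.norm.sf(z) if np.isfinite(z) else np.nan
            imp_rows.append({
                "variable": v, "wg": wg, "N": best_count[v],
                "coefficient": coef, "std_error": se, "z": z, "p": p,
            })
        table = (pd.DataFrame(imp_rows)
                 .sort_values(["wg", "N"], ascending=False)
                 .reset_index(drop=True))
        return DriverImportanceResults(
            model=self, table=table, n_iter=n_done, n_points=n_points,
            n_skipped=n_skipped, wg_mode=wg_mode,
            iterations=pd.DataFrame(iter_log),
        )


@dataclass
class DriverImportanceResults:
    """Aggregated variable importance and model-averaged coefficients."""

    model: DriverImportanceModel
    table: pd.DataFrame
    n_iter: int
    n_points: int
    n_skipped: int
    wg_mode: str
    iterations: pd.DataFrame = field(repr=False, default=None)

    @property
    def importance(self) -> pd.DataFrame:
        """wg and N per variable (the ranking table)."""
        return self.table[["variable", "wg", "N"]]

    @property
    def coefficients(self) -> pd.DataFrame:
        """Conditionally model-averaged coefficients with unconditional SEs."""
        return self.table[["variable", "coefficient", "std_error", "z", "p"]]

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        out.attrs["n_iter"] = self.n_iter
        out.attrs["n_points"] = self.n_points
        return out

    def __repr__(self) -> str:
        top = self.table.iloc[0]
        return (f"<DriverImportanceResults {self.n_iter} iterations x "
                f"{self.n_points} points; top driver {top['variable']} "
                f"(wg={top['wg']:.2f}, N={int(top['N'])})>")
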
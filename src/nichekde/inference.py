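"""Site-year analysis table and Gaussian mixed models.

Three model designs probe density-dependent competition between the two
species, always with a random intercept per study site:

* overlap ~ great-bustard density (sympatric, overlap-eligible site-years);
* niche breadth / position ~ great-bustard presence + the matching
  environmental-niche covariate (all site-years) — the ecological-release
  contrast between sympatry and allopatry;
* niche breadth / position ~ little-bustard density + great-bustard
  density + environmental covariate (sympatric site-years only) — the
  density-dependent test.

Estimates and standard errors come from REML fits; likelihood-ratio
chi-squares per fixed term come from ML refits with and without the term.
The environmental covariate controls for the functional response of
habitat use to habitat availability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats


class InsufficientDataError(ValueError):
    """Too few usable records to fit a model."""


@dataclass(frozen=True)
class TermResult:
    name: str
    estimate: float
    se: float
    tvalue: float
    p_wald: float
    lrt_chi2: float = np.nan
    p_lrt: float = np.nan


@dataclass(frozen=True)
class ModelResult:
    """One fitted mixed model (or its degenerate fallback)."""

    response: str
    terms: tuple[TermResult, ...]
    intercept: float
    random_intercept_var: float
    residual_var: float
    n: int
    n_groups: int
    singular: bool = False
    degenerate: bool = False
    converged: bool = True

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_rows(self, label: str = "") -> list[dict]:
        rows = []
        for t in self.terms:
            rows.append(
                {
                    "niche": label,
                    "response": self.response,
                    "term": t.name,
                    "estimate": t.estimate,
                    "se": t.se,
                    "t": t.tvalue,
                    "chi2": t.lrt_chi2,
                    "p_wald": t.p_wald,
                    "p_lrt": t.p_lrt,
                    "n": self.n,
                    "singular": self.singular,
                    "degenerate": self.degenerate,
                }
            )
        return rows


def site_density(observations: pd.DataFrame, mcp_area_km2: float, species: str) -> float:
    """Density inside the MCP: little bustard = male observations per
    km^2; great bustard = all individuals per km^2."""
    if mcp_area_km2 <= 0:
        raise ValueError("MCP area must be positive")
    sub = observations[observations["species"] == species]
    if species == "little_bustard":
        return float(len(sub) / mcp_area_km2)
    return float(sub["count"].sum() / mcp_area_km2)


def _ols_fallback(y: np.ndarray, x: np.ndarray, names: list[str], response: str,
                  n_groups: int, degenerate: bool) -> ModelResult:
    """Least-squares estimates when the mixed fit is degenerate (e.g. an
    exactly collinear or zero-residual design)."""
    xmat = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
    resid = y - xmat @ beta
    dof = max(len(y) - xmat.shape[1], 1)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(xmat.T @ xmat)
    ses = np.sqrt(np.maximum(np.diag(xtx_inv) * s2, 0.0))
    terms = []
    for j, name in enumerate(names, start=1):
        est = float(beta[j])
        se = float(ses[j])
        tval = est / se if se > 0 else (0.0 if est == 0 else np.inf)
        p = 2 * stats.t.sf(abs(tval), dof) if se > 0 else (1.0 if est == 0 else 0.0)
        terms.append(TermResult(name, est, se, tval, p))
    return ModelResult(
        response=response, terms=tuple(terms), intercept=float(beta[0]),
        random_intercept_var=0.0, residual_var=s2, n=len(y),
        n_groups=n_groups, singular=True, degenerate=degenerate, converged=True,
    )


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed_terms: list[str],
    group: str = "site",
    compute_lrt: bool = True,
) -> ModelResult:
    """Gaussian linear mixed model with a random intercept per group.

    REML for estimates/SEs and Wald t statistics; per-term likelihood
    ratio chi-squares from ML refits with and without the term.  A zero
    random-intercept variance is a boundary fit, flagged but not an
    error; exactly degenerate designs (zero residual variance) fall back
    to least squares with a ``degenerate`` flag.
    """
    cols = [response, group, *fixed_terms]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns missing from table: {missing}")
    data = table[cols].dropna()
    n_groups = data[group].nunique()
    if len(data) < len(fixed_terms) + 2 or n_groups < 2:
        raise InsufficientDataError(
            f"{len(data)} usable rows / {n_groups} groups is not enough to fit "
            f"{response} ~ {' + '.join(fixed_terms)}"
        )
    y = data[response].to_numpy(dtype=float)
    x = data[fixed_terms].to_numpy(dtype=float)

    if np.var(y) == 0:
        return _ols_fallback(y, x, fixed_terms, response, n_groups, degenerate=True)

    formula = f"{response} ~ {' + '.join(fixed_terms)}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            reml = smf.mixedlm(formula, data, groups=data[group]).fit(reml=True)
            resid_var = float(reml.scale)
            if not np.isfinite(resid_var) or resid_var < 1e-12 * np.var(y):
                raise np.linalg.LinAlgError("zero residual variance")
        except (np.linalg.LinAlgError, ValueError):
            return _ols_fallback(y, x, fixed_terms, response, n_groups, degenerate=True)

        ll_full = np.nan
        if compute_lrt:
            try:
                ll_full = smf.mixedlm(formula, data, groups=data[group]).fit(
                    reml=False
                ).llf
            except (np.linalg.LinAlgError, ValueError):
                compute_lrt = False

        terms = []
        df_resid = max(len(data) - len(fixed_terms) - 1, 1)
        for name in fixed_terms:
            est = float(reml.params[name])
            se = float(reml.bse[name])
            tval = est / se if se > 0 else np.nan
            # t reference with residual df: the normal approximation is
            # anticonservative at the sample sizes these designs run at
            p_wald = (
                float(2 * stats.t.sf(abs(tval), df_resid))
                if np.isfinite(tval)
                else np.nan
            )
            chi2 = p_lrt = np.nan
            if compute_lrt and np.isfinite(ll_full):
                reduced = [t for t in fixed_terms if t != name]
                rformula = f"{response} ~ {' + '.join(reduced) if reduced else '1'}"
                try:
                    ll_red = smf.mixedlm(rformula, data, groups=data[group]).fit(
                        reml=False
                    ).llf
                    chi2 = max(0.0, 2.0 * (ll_full - ll_red))
                    p_lrt = float(stats.chi2.sf(chi2, df=1))
                except (np.linalg.LinAlgError, ValueError):
                    pass
            terms.append(TermResult(name, est, se, tval, p_wald, chi2, p_lrt))

    group_var = float(reml.cov_re.iloc[0, 0])
    return ModelResult(
        response=response,
        terms=tuple(terms),
        intercept=float(reml.params["Intercept"]),
        random_intercept_var=group_var,
        residual_var=resid_var,
        n=len(data),
        n_groups=n_groups,
        singular=bool(group_var < 1e-10),
        converged=bool(getattr(reml, "converged", True)),
    )


# ---------------------------------------------------------------------------
# the three analysis designs
# ---------------------------------------------------------------------------

POSITION_DIMS = ("pos_dim1", "pos_dim2")


def _axis_pair_columns(axis_pair: str) -> dict[str, tuple[str, str]]:
    """response column -> (little-bustard column, environmental column)."""
    ap = axis_pair.replace("-", "_").lower()
    return {
        "breadth": (f"lb_breadth_{ap}", f"env_breadth_{ap}"),
        "pos_dim1": (f"lb_pos1_{ap}", f"env_pos1_{ap}"),
        "pos_dim2": (f"lb_pos2_{ap}", f"env_pos2_{ap}"),
    }


def overlap_analysis(
    records: pd.DataFrame, axis_pairs: list[str], compute_lrt: bool = False
) -> dict[str, ModelResult]:
    """Overlap ~ great-bustard density, per axis pair, on the sympatric
    overlap-eligible records."""
    out: dict[str, ModelResult] = {}
    for ap in axis_pairs:
        col = f"overlap_{ap.replace('-', '_').lower()}"
        sub = records.dropna(subset=[col])
        if len(sub) < 3:
            raise InsufficientDataError(
                f"only {len(sub)} records with overlap values for {ap}"
            )
        res = fit_lmm(
            sub.rename(columns={col: "overlap"}),
            "overlap",
            ["gb_density"],
            compute_lrt=compute_lrt,
        )
        out[ap] = res
    return out


def shift_analysis_presence(
    records: pd.DataFrame,
    axis_pairs: list[str],
    responses: tuple[str, ...] = ("breadth", "pos_dim1", "pos_dim2"),
    compute_lrt: bool = True,
) -> dict[tuple[str, str], ModelResult]:
    """Ecological-release design: response ~ gb_present + environmental
    covariate, all site-years."""
    out = {}
    for ap in axis_pairs:
        colmap = _axis_pair_columns(ap)
        for resp in responses:
            lb_col, env_col = colmap[resp]
            sub = records.dropna(subset=[lb_col, env_col]).copy()
            sub["gb_present"] = sub["gb_present"].astype(float)
            res = fit_lmm(
                sub.rename(columns={lb_col: "lb_resp", env_col: "env_cov"}),
                "lb_resp",
                ["gb_present", "env_cov"],
                compute_lrt=compute_lrt,
            )
            out[(ap, resp)] = res
    return out


def shift_analysis_density(
    records: pd.DataFrame,
    axis_pairs: list[str],
    responses: tuple[str, ...] = ("breadth", "pos_dim1", "pos_dim2"),
    compute_lrt: bool = False,
) -> dict[tuple[str, str], ModelResult]:
    """Density-dependent design: response ~ lb_density + gb_density +
    environmental covariate, sympatric site-years only."""
    sym = records[records["gb_present"]]
    out = {}
    for ap in axis_pairs:
        colmap = _axis_pair_columns(ap)
        for resp in responses:
            lb_col, env_col = colmap[resp]
            sub = sym.dropna(subset=[lb_col, env_col]).copy()
            res = fit_lmm(
                sub.rename(columns={lb_col: "lb_resp", env_col: "env_cov"}),
                "lb_resp",
                ["lb_density", "gb_density", "env_cov"],
                compute_lrt=compute_lrt,
            )
            out[(ap, resp)] = res
    return out


def results_table(results: dict, kind: str) -> pd.DataFrame:
    """Flatten a dict of ModelResults into a tidy table (one row per
    fixed term) matching the published table layouts."""
    rows: list[dict] = []
    for key, res in results.items():
        if isinstance(key, tuple):
            ap, resp = key
            rows.extend(r | {"response": resp} for r in res.to_rows(label=ap))
        else:
            rows.extend(res.to_rows(label=key))
    df = pd.DataFrame(rows)
    df.insert(0, "analysis", kind)
    return df
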
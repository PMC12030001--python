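"""Quantitative genetics for balanced multi-year trials.

Balanced-design ANOVA, method-of-moments variance components from
expected mean squares (EMS), progeny-mean heritability, genetic
correlations from the genetic variance-covariance contrast, Fisher's
LSD with a compact letter display, and indirect-selection efficiency.

For a balanced layout (every genotype x year x rep cell observed once)
the EMS estimators coincide in expectation with REML from the analogous
mixed model, while being fully closed-form:

    sigma2_e   = MS_Error
    sigma2_GxE = (MS_GxY  - MS_Error)    / nR
    sigma2_G   = (MS_G    - MS_GxY)      / (nE * nR)
    sigma2_E   = (MS_Year - MS_Rep(Year))/ (nG * nR)

negative solutions are truncated at zero.  Progeny-mean heritability is

    H2 = sigma2_G / (sigma2_G + sigma2_GxE/nE + sigma2_e/(nE*nR))

and the efficiency of indirect selection relative to direct selection is
EI = |rG| * h_X / h_Y with h the square roots of the secondary- and
primary-trait heritabilities.  Standard errors of H2 and rG come from a
delete-one-genotype jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENO, YEAR, REP, BLOCK = "genotype", "year", "rep", "block"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """EMS variance components of one trait in a balanced trial."""

    sigma2_g: float
    sigma2_env: float
    sigma2_gxe: float
    sigma2_e: float
    n_env: int
    n_rep: int
    se_h2: float = float("nan")

    def heritability(self) -> float:
        return heritability(self)


@dataclass
class GeneticCovariance:
    trait_x: str
    trait_y: str
    cov_g: float
    sigma2_g_x: float
    sigma2_g_y: float
    r_g: float
    se_r_g: float = float("nan")


@dataclass
class SelectionEfficiency:
    r_g: float
    h_x: float
    h_y: float
    ei_percent: float


# ---------------------------------------------------------------------------
# balanced ANOVA
# ---------------------------------------------------------------------------

def _check_balanced(table: pd.DataFrame) -> tuple[int, int, int]:
    counts = table.groupby([GENO, YEAR, REP]).size()
    g = table[GENO].nunique()
    e = table[YEAR].nunique()
    r = table[REP].nunique()
    if len(counts) != g * e * r or (counts != 1).any():
        raise ValueError(
            "unbalanced table: the EMS estimators require every "
            "genotype x year x rep cell exactly once")
    return g, e, r


def anova(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Balanced multifactorial ANOVA.

    Sources: Genotype, Year, Replication(Year), Block(Year),
    Genotype:Year, Error; all F tests are against the error mean square.
    The block stratum is included when the table carries a ``block``
    column balanced within years.
    """
    g, e, r = _check_balanced(table)
    y = table[trait].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    def group_ss(keys: list[str]) -> float:
        m = table.groupby(keys)[trait].transform("mean").to_numpy()
        return float(((m - grand) ** 2).sum())

    ss_g = group_ss([GENO])
    ss_y = group_ss([YEAR])
    ss_ry = group_ss([YEAR, REP]) - ss_y
    ss_gy = group_ss([GENO, YEAR]) - ss_g - ss_y

    rows = [("Genotype", g - 1, ss_g), ("Year", e - 1, ss_y),
            ("Replication", e * (r - 1), ss_ry)]
    ss_by = 0.0
    if BLOCK in table.columns:
        b = table[BLOCK].nunique()
        ss_by = group_ss([YEAR, BLOCK]) - ss_y
        rows.append(("Block", e * (b - 1), ss_by))
    rows.append(("Genotype:Year", (g - 1) * (e - 1), ss_gy))
    ss_err = ss_total - ss_g - ss_y - ss_ry - ss_by - ss_gy
    df_err = n - 1 - sum(df for _, df, _ in rows)
    rows.append(("Error", df_err, ss_err))

    out = pd.DataFrame(rows, columns=["source", "df", "ss"])
    out["ms"] = out["ss"] / out["df"]
    ms_err = out.loc[out["source"] == "Error", "ms"].iloc[0]
    out["F"] = np.where(out["source"] == "Error", np.nan, out["ms"] / ms_err)
    out["p"] = stats.f.sf(out["F"], out["df"], df_err)
    return out


# ---------------------------------------------------------------------------
# variance components and heritability
# ---------------------------------------------------------------------------

def _components_raw(table: pd.DataFrame, trait: str) -> tuple[float, ...]:
    aov = anova(table, trait).set_index("source")
    g = table[GENO].nunique()
    e = table[YEAR].nunique()
    r = table[REP].nunique()
    ms_err = aov.loc["Error", "ms"]
    ms_gy = aov.loc["Genotype:Year", "ms"]
    ms_g = aov.loc["Genotype", "ms"]
    ms_y = aov.loc["Year", "ms"]
    ms_ry = aov.loc["Replication", "ms"]
    s2_e = ms_err
    s2_gxe = (ms_gy - ms_err) / r
    s2_g = (ms_g - ms_gy) / (e * r)
    s2_env = (ms_y - ms_ry) / (g * r)
    return s2_g, s2_env, s2_gxe, s2_e, g, e, r


def estimate_variance_components(
    table: pd.DataFrame, trait: str, jackknife: bool = True
) -> VarianceComponents:
    """Method-of-moments variance components from the EMS contrasts.

    Negative solutions are truncated at zero; the standard error of the
    heritability comes from a delete-one-genotype jackknife.
    """
    s2_g, s2_env, s2_gxe, s2_e, g, e, r = _components_raw(table, trait)
    vc = VarianceComponents(
        sigma2_g=max(0.0, s2_g), sigma2_env=max(0.0, s2_env),
        sigma2_gxe=max(0.0, s2_gxe), sigma2_e=max(0.0, s2_e),
        n_env=e, n_rep=r)
    if jackknife and g > 2:
        h2_del = []
        for geno in table[GENO].unique():
            sub = table[table[GENO] != geno]
            sg, _, sgxe, se, _, ee, rr = _components_raw(sub, trait)
            sub_vc = VarianceComponents(
                sigma2_g=max(0.0, sg), sigma2_env=0.0,
                sigma2_gxe=max(0.0, sgxe), sigma2_e=max(0.0, se),
                n_env=ee, n_rep=rr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                h2_del.append(heritability(sub_vc))
        h2_del = np.asarray(h2_del)
        vc.se_h2 = float(np.sqrt((g - 1) / g * np.nansum(
            (h2_del - np.nanmean(h2_del)) ** 2)))
    return vc


def heritability(vc: VarianceComponents) -> float:
    """Progeny-mean heritability H2 in [0, 1]."""
    if vc.n_env < 1 or vc.n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    denom = vc.sigma2_g + vc.sigma2_gxe / vc.n_env + vc.sigma2_e / (
        vc.n_env * vc.n_rep)
    if denom <= 0:
        warnings.warn("all variance components zero: H2 undefined",
                      stacklevel=2)
        return float("nan")
    return float(vc.sigma2_g / denom)


# ---------------------------------------------------------------------------
# genetic correlation
# ---------------------------------------------------------------------------

def _cov_g_raw(table: pd.DataFrame, tx: str, ty: str) -> tuple[float, float, float]:
    g, e, r = _check_balanced(table)
    x = table[tx].to_numpy(dtype=float)
    y = table[ty].to_numpy(dtype=float)
    xg = table.groupby(GENO)[tx].mean()
    yg = table.groupby(GENO)[ty].mean()
    xy_g = float(((xg - x.mean()) * (yg - y.mean())).sum()) * e * r / (g - 1)
    xgy = table.groupby([GENO, YEAR])[tx].mean()
    ygy = table.groupby([GENO, YEAR])[ty].mean()
    xm_y = table.groupby(YEAR)[tx].mean()
    ym_y = table.groupby(YEAR)[ty].mean()
    dx = xgy - xg.reindex(xgy.index.get_level_values(0)).to_numpy() \
        - xm_y.reindex(xgy.index.get_level_values(1)).to_numpy() + x.mean()
    dy = ygy - yg.reindex(ygy.index.get_level_values(0)).to_numpy() \
        - ym_y.reindex(ygy.index.get_level_values(1)).to_numpy() + y.mean()
    xy_gy = float((dx * dy).sum()) * r / ((g - 1) * (e - 1))
    cov_g = (xy_g - xy_gy) / (e * r)
    sx = _components_raw(table, tx)[0]
    sy = _components_raw(table, ty)[0]
    return cov_g, sx, sy


def genetic_covariance(
    table: pd.DataFrame, trait_x: str, trait_y: str, jackknife: bool = True
) -> GeneticCovariance:
    """Genetic covariance and correlation via the EMS contrast applied to
    mean cross-products, rG = CovG / sqrt(sigma2_G(X) * sigma2_G(Y)).

    rG is reported unclipped (|rG| > 1 can occur through estimation
    noise, with a warning); a non-positive genetic variance makes rG
    undefined (NaN) rather than clipped.
    """
    cov_g, sx, sy = _cov_g_raw(table, trait_x, trait_y)
    if sx <= 0 or sy <= 0:
        warnings.warn("non-positive genetic variance: rG undefined",
                      stacklevel=2)
        r_g = float("nan")
    else:
        r_g = cov_g / np.sqrt(sx * sy)
        if abs(r_g) > 1 + 1e-9:
            warnings.warn(f"|rG| = {abs(r_g):.3f} > 1 (estimation noise); "
                          "reported unclipped", stacklevel=2)
    out = GeneticCovariance(trait_x=trait_x, trait_y=trait_y, cov_g=cov_g,
                            sigma2_g_x=max(0.0, sx), sigma2_g_y=max(0.0, sy),
                            r_g=float(r_g))
    g = table[GENO].nunique()
    if jackknife and g > 2 and np.isfinite(r_g):
        rs = []
        for geno in table[GENO].unique():
            sub = table[table[GENO] != geno]
            c, a, b = _cov_g_raw(sub, trait_x, trait_y)
            rs.append(c / np.sqrt(a * b) if a > 0 and b > 0 else np.nan)
        rs = np.asarray(rs)
        out.se_r_g = float(np.sqrt((g - 1) / g * np.nansum(
            (rs - np.nanmean(rs)) ** 2)))
    return out


def pearson(table: pd.DataFrame, trait_x: str, trait_y: str) -> tuple[float, float, str]:
    """Plot-level Pearson correlation with significance stars.

    Returns ``(r, p, stars)`` with stars ``*``/``**``/``***`` at the
    0.05 / 0.01 / 0.001 levels.
    """
    x = table[trait_x].to_numpy(dtype=float)
    y = table[trait_y].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), ""
    r, p = stats.pearsonr(x, y)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return float(r), float(p), stars


# ---------------------------------------------------------------------------
# selection efficiency, LSD, SE
# ---------------------------------------------------------------------------

def indirect_selection_efficiency(
    r_g: float, h2_secondary: float, h2_primary: float
) -> SelectionEfficiency:
    """EI = |rG| * h_X / h_Y, as a percentage of direct selection."""
    if not np.isfinite(r_g) or not np.isfinite(h2_secondary) \
            or not np.isfinite(h2_primary):
        raise ValueError("inputs must be finite")
    if h2_secondary < 0:
        raise ValueError("secondary-trait heritability must be >= 0")
    if h2_primary <= 0:
        raise ValueError("primary-trait heritability must be > 0")
    h_x = float(np.sqrt(h2_secondary))
    h_y = float(np.sqrt(h2_primary))
    ei = 100.0 * abs(r_g) * h_x / h_y
    return SelectionEfficiency(r_g=float(r_g), h_x=h_x, h_y=h_y,
                               ei_percent=float(ei))


def fisher_lsd(
    anova_table: pd.DataFrame,
    means: pd.Series,
    n_per_mean: int,
    level: float = 0.05,
) -> pd.DataFrame:
    """Fisher's least significant difference with a compact letter display.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MS_error / n_per_mean);
    means closer than the LSD share a letter.
    """
    if n_per_mean <= 0:
        raise ValueError("n_per_mean must be positive")
    err = anova_table.set_index("source").loc["Error"]
    lsd = float(stats.t.ppf(1 - level / 2, err["df"])
                * np.sqrt(2 * err["ms"] / n_per_mean))
    order = means.sort_values(ascending=False)
    m = order.to_numpy()
    # maximal runs of mutually non-significant (|diff| < LSD) means
    intervals = []
    for i in range(len(m)):
        j = i
        while j + 1 < len(m) and m[i] - m[j + 1] < lsd:
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                          for o in intervals)]
    letters = {name: "" for name in order.index}
    for letter, (i, j) in zip("abcdefghijklmnopqrstuvwxyz", maximal):
        for name in order.index[i:j + 1]:
            letters[name] += letter
    return pd.DataFrame({
        "mean": order,
        "group": [letters[n] for n in order.index],
    }, index=order.index).assign(lsd=lsd)


def standard_error(values) -> float:
    """Standard error of the mean, s / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def standardize_gy(
    plot_weight_kg, sample_moisture_pct, plot_area: float = 7.0
) -> np.ndarray:
    """Grain yield in t/ha standardized to 14% grain moisture:
    GY = (W_kg * (100 - moisture)/86 * 10000/area) / 1000."""
    w = np.asarray(plot_weight_kg, dtype=float)
    m = np.asarray(sample_moisture_pct, dtype=float)
    return w * (100.0 - m) / 86.0 * (10000.0 / plot_area) / 1000.0
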
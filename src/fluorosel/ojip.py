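"""OJIP transient analysis and the JIP-test parameter engine.

A dark-adapted leaf exposed to saturating light emits chlorophyll-a
fluorescence that rises from the minimal level O through two intermediate
plateaus (J at ~2 ms, I at ~30 ms) to the peak P (= Fm).  The JIP-test
reads a small set of landmark fluorescence values off this polyphasic
rise and converts them into quantum yields, flux ratios, and performance
indices describing the energy cascade through photosystem II.

Conventions used here (Handy-PEA style exports):

* the O level ``F0`` is the reading at the grid point nearest 50 µs — the
  first reliable point after the instrument's light rise;
* marker signals F1..F5 sit at 50 µs, 100 µs, 300 µs, 2 ms and 30 ms;
* ``Fm`` is the curve maximum (first occurrence), ``t_Fm`` its time;
* the complementary area is taken between the curve and the horizontal
  line ``F = Fm`` from ``t(F0)`` to ``t_Fm`` by the trapezoidal rule.

Kinetic quantities (M0, Sm, N, ...) are expressed per millisecond, the
customary JIP-test time unit; times themselves are kept in seconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: landmark marker times, seconds
LANDMARK_TIMES = {
    "F1": 50e-6,
    "F2": 100e-6,
    "F3": 300e-6,
    "F4": 2e-3,   # J step
    "F5": 30e-3,  # I step
}

#: time of the O (zero-level) reading, seconds
F0_TIME = 50e-6

KEY_COLUMNS = ["genotype", "year", "rep", "plant"]
PLOT_KEYS = ["genotype", "year", "rep"]


def default_time_grid(n: int = 118, t_min: float = 20e-6, t_max: float = 1.0) -> np.ndarray:
    """Quasi-logarithmic acquisition grid from 20 µs to 1 s (seconds)."""
    return np.geomspace(t_min, t_max, n)


def time_columns(times: np.ndarray) -> list[str]:
    """Column labels ``t_<microseconds>`` used in wide transient CSVs."""
    return [f"t_{t * 1e6:.4f}" for t in np.asarray(times)]


def parse_time_columns(columns: Iterable[str]) -> np.ndarray:
    """Recover the time grid (seconds) from ``t_<microseconds>`` labels."""
    return np.array([float(c[2:]) * 1e-6 for c in columns])


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class Transient:
    """One plant's fluorescence induction curve.

    times are strictly increasing (seconds); values are positive
    arbitrary fluorescence units of equal length.
    """

    times: np.ndarray
    values: np.ndarray
    genotype: str | None = None
    year: int | None = None
    rep: int | None = None
    plant: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("a transient needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("fluorescence values must be finite and > 0")


@dataclass
class Landmarks:
    """OJIP landmark readings of a single transient."""

    F0: float
    F1: float
    F2: float
    F3: float
    F4: float
    F5: float
    Fm: float
    t_Fm: float
    area: float


@dataclass
class NormalizedTransient:
    """Relative variable fluorescence V(t) = (F - F0)/(Fm - F0)."""

    times: np.ndarray
    V: np.ndarray


@dataclass
class JIPParameters:
    """Derived biophysical parameter vector for one measurement."""

    values: "pd.Series"

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    @property
    def names(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# parameter roster
# ---------------------------------------------------------------------------

#: canonical ordered 56-parameter JIP-test roster
PARAM_NAMES_56 = [
    # landmark-derived raw quantities
    "t_Fm", "area", "F1", "F2", "F3", "F4", "F5",
    # variable fluorescence
    "Fv", "Fv_F0", "V100us", "V300us",
    # relative kinetics
    "VJ", "VI", "M0", "dVG_dt0", "Sm", "N",
    "Ss", "Sm_tFm",
    # quantum yields and probabilities
    "phi_Po", "phi_Do", "psi_Eo", "phi_Eo", "delta_Ro", "phi_Ro",
    "psi_Ro", "gamma_RC",
    # reaction-centre density
    "RC_ABS", "ABS_RC",
    # specific fluxes per reaction centre
    "TR0_RC", "ET0_RC", "RE0_RC", "DI0_RC",
    # flux ratios per absorption
    "TR0_ABS", "ET0_ABS", "RE0_ABS", "DI0_ABS",
    # phenomenological fluxes per excited cross-section (at F0)
    "ABS_CS0", "TR0_CS0", "ET0_CS0", "RE0_CS0", "DI0_CS0", "RC_CS0",
    # phenomenological fluxes per excited cross-section (at Fm)
    "ABS_CSm", "TR0_CSm", "ET0_CSm", "RE0_CSm", "DI0_CSm", "RC_CSm",
    # performance indices
    "PI_ABS", "PI_total", "SFI_ABS", "PI_CS0", "PI_CSm",
    "DF_ABS", "DF_total",
]

#: the 56 set plus the raw F0 and Fm signals
PARAM_NAMES_58 = ["F0", "Fm"] + PARAM_NAMES_56

PARAM_PRESETS = {"jip56": PARAM_NAMES_56, "extended58": PARAM_NAMES_58}

#: parameters invariant under a pure gain change F -> c*F
SCALE_INVARIANT = [
    "t_Fm", "Fv_F0", "V100us", "V300us", "VJ", "VI", "M0", "dVG_dt0",
    "Sm", "N", "Ss", "Sm_tFm",
    "phi_Po", "phi_Do", "psi_Eo", "phi_Eo", "delta_Ro", "phi_Ro",
    "psi_Ro", "gamma_RC", "RC_ABS", "ABS_RC",
    "TR0_RC", "ET0_RC", "RE0_RC", "DI0_RC",
    "TR0_ABS", "ET0_ABS", "RE0_ABS", "DI0_ABS",
    "PI_ABS", "PI_total", "SFI_ABS", "DF_ABS", "DF_total",
]

#: parameters additionally invariant under the affine map F -> (F-F0)/(Fm-F0)
AFFINE_INVARIANT = [
    "t_Fm", "V100us", "V300us", "VJ", "VI", "M0", "dVG_dt0", "Sm", "N",
    "Ss", "Sm_tFm", "psi_Eo", "delta_Ro", "psi_Ro",
]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _nearest_index(times: np.ndarray, target: float, name: str) -> int:
    i = int(np.argmin(np.abs(times - target)))
    # tolerance: one local grid step
    lo = times[max(i - 1, 0)]
    hi = times[min(i + 1, len(times) - 1)]
    step = max(hi - times[i], times[i] - lo)
    if abs(times[i] - target) > step:
        raise ValueError(
            f"time grid does not cover the {name} landmark at {target:g} s"
        )
    return i


def extract_landmarks(transient: Transient) -> Landmarks:
    """Read the OJIP landmarks off a transient.

    F0 and F1..F5 come from the grid points nearest their marker times
    (no interpolation; tolerance of one grid step), Fm is the curve
    maximum, and the complementary area is the trapezoidal integral of
    ``Fm - F(t)`` between ``t(F0)`` and ``t_Fm``.
    """
    t, f = transient.times, transient.values
    i0 = _nearest_index(t, F0_TIME, "F0")
    marks = {
        name: f[_nearest_index(t, tt, name)] for name, tt in LANDMARK_TIMES.items()
    }
    i_max = int(np.argmax(f))
    fm = float(f[i_max])
    sl = slice(i0, i_max + 1)
    area = float(np.trapezoid(fm - f[sl], t[sl])) if i_max > i0 else 0.0
    return Landmarks(
        F0=float(f[i0]),
        F1=float(marks["F1"]),
        F2=float(marks["F2"]),
        F3=float(marks["F3"]),
        F4=float(marks["F4"]),
        F5=float(marks["F5"]),
        Fm=fm,
        t_Fm=float(t[i_max]),
        area=area,
    )


def normalize(transient: Transient, lm: Landmarks | None = None) -> NormalizedTransient:
    """Normalize a transient by its total variable fluorescence Fm - F0."""
    if lm is None:
        lm = extract_landmarks(transient)
    fv = lm.Fm - lm.F0
    if fv <= 0:
        raise ValueError("degenerate transient: Fm equals F0")
    return NormalizedTransient(times=transient.times.copy(),
                               V=(transient.values - lm.F0) / fv)


def pi_abs(phi_po: float, psi_eo: float, rc_abs: float) -> float:
    """Performance index on absorption basis.

    PI_ABS = (RC/ABS) * phi_Po/(1-phi_Po) * psi_Eo/(1-psi_Eo), the
    product of the reaction-centre density term and the two yield odds.
    """
    return rc_abs * phi_po / (1.0 - phi_po) * psi_eo / (1.0 - psi_eo)


def _jip_arrays(F0, F1, F2, F3, F4, F5, Fm, t_Fm, area) -> dict[str, np.ndarray]:
    """Vectorized JIP-test computation on landmark arrays.

    Undefined ratios (degenerate Fv, VJ or phi_Po at 0/1, non-positive
    M0, saturated delta_Ro) are emitted as NaN rather than infinities.
    """
    F0, F1, F2, F3, F4, F5, Fm, t_Fm, area = (
        np.asarray(a, dtype=float)
        for a in (F0, F1, F2, F3, F4, F5, Fm, t_Fm, area)
    )
    out: dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        Fv = Fm - F0
        bad_fv = Fv <= 0

        def safe(num, den, bad=None):
            r = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
            if bad is not None:
                r = np.where(bad, np.nan, r)
            return r

        out["F0"], out["Fm"] = F0, Fm
        out["t_Fm"], out["area"] = t_Fm, area
        out["F1"], out["F2"], out["F3"], out["F4"], out["F5"] = F1, F2, F3, F4, F5
        out["Fv"] = Fv
        out["Fv_F0"] = safe(Fv, F0)
        out["V100us"] = safe(F2 - F0, Fv, bad_fv)
        out["V300us"] = safe(F3 - F0, Fv, bad_fv)
        VJ = safe(F4 - F0, Fv, bad_fv)
        VI = safe(F5 - F0, Fv, bad_fv)
        out["VJ"], out["VI"] = VJ, VI
        # initial slope of relative variable fluorescence, per ms
        M0 = 4.0 * safe(F3 - F1, Fm - F1)
        out["M0"] = M0
        # initial inclination of the raw curve between 50 and 100 µs, per ms
        out["dVG_dt0"] = safe(F2 - F1, (Fm - F1) * 0.05)
        Sm = 1000.0 * safe(area, Fv, bad_fv)  # normalized area, ms
        out["Sm"] = Sm
        bad_vj = bad_fv | ~np.isfinite(VJ) | (VJ <= 0) | (VJ >= 1)
        bad_m0 = ~np.isfinite(M0) | (M0 <= 0)
        out["N"] = np.where(bad_vj | bad_m0, np.nan, Sm * M0 / VJ)
        out["Ss"] = np.where(bad_m0, np.nan, VJ / M0)
        out["Sm_tFm"] = safe(Sm, t_Fm * 1000.0)

        phi_po = safe(Fv, Fm, bad_fv)
        bad_phi = bad_fv | ~np.isfinite(phi_po) | (phi_po <= 0) | (phi_po >= 1)
        psi_eo = 1.0 - VJ
        delta_ro = np.where(bad_vj, np.nan, (1.0 - VI) / (1.0 - VJ))
        out["phi_Po"] = phi_po
        out["phi_Do"] = safe(F0, Fm)
        out["psi_Eo"] = psi_eo
        out["phi_Eo"] = phi_po * psi_eo
        out["delta_Ro"] = delta_ro
        out["phi_Ro"] = phi_po * psi_eo * delta_ro
        out["psi_Ro"] = psi_eo * delta_ro

        rc_abs = np.where(bad_m0 | bad_phi | bad_vj, np.nan, phi_po * VJ / M0)
        out["RC_ABS"] = rc_abs
        out["gamma_RC"] = rc_abs / (1.0 + rc_abs)
        out["ABS_RC"] = safe(np.ones_like(rc_abs), rc_abs)
        tr0_rc = np.where(bad_m0 | bad_vj, np.nan, M0 / VJ)
        out["TR0_RC"] = tr0_rc
        out["ET0_RC"] = tr0_rc * psi_eo
        out["RE0_RC"] = tr0_rc * psi_eo * delta_ro
        out["DI0_RC"] = out["ABS_RC"] - tr0_rc
        out["TR0_ABS"] = phi_po
        out["ET0_ABS"] = out["phi_Eo"]
        out["RE0_ABS"] = out["phi_Ro"]
        out["DI0_ABS"] = out["phi_Do"]
        for tag, cs in (("CS0", F0), ("CSm", Fm)):
            out[f"ABS_{tag}"] = cs
            out[f"TR0_{tag}"] = phi_po * cs
            out[f"ET0_{tag}"] = out["phi_Eo"] * cs
            out[f"RE0_{tag}"] = out["phi_Ro"] * cs
            out[f"DI0_{tag}"] = cs - phi_po * cs
            out[f"RC_{tag}"] = rc_abs * cs

        pi = np.where(
            bad_phi | bad_vj,
            np.nan,
            rc_abs * phi_po / (1.0 - phi_po) * psi_eo / (1.0 - psi_eo),
        )
        out["PI_ABS"] = pi
        bad_dro = ~np.isfinite(delta_ro) | (delta_ro <= 0) | (delta_ro >= 1)
        out["PI_total"] = np.where(bad_dro, np.nan, pi * delta_ro / (1.0 - delta_ro))
        out["SFI_ABS"] = rc_abs * phi_po * psi_eo
        out["PI_CS0"] = pi * F0
        out["PI_CSm"] = pi * Fm
        out["DF_ABS"] = np.where(pi > 0, np.log10(np.where(pi > 0, pi, 1.0)), np.nan)
        pit = out["PI_total"]
        out["DF_total"] = np.where(pit > 0, np.log10(np.where(pit > 0, pit, 1.0)), np.nan)
    return out


def compute_jip(lm: Landmarks, preset: str = "extended58") -> JIPParameters:
    """Derive the JIP-test biophysical parameter vector from landmarks."""
    if lm.Fm <= lm.F0 or lm.F0 <= 0:
        raise ValueError("compute_jip requires Fm > F0 > 0")
    names = PARAM_PRESETS[preset]
    arrays = _jip_arrays(
        lm.F0, lm.F1, lm.F2, lm.F3, lm.F4, lm.F5, lm.Fm, lm.t_Fm, lm.area
    )
    vals = pd.Series({n: float(arrays[n]) for n in names}, name="jip")
    if vals.isna().any():
        logger.warning(
            "undefined JIP parameters (degenerate ratios): %s",
            ", ".join(vals.index[vals.isna()]),
        )
    return JIPParameters(values=vals)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def transients_to_frame(transients: Sequence[Transient]) -> pd.DataFrame:
    """Wide DataFrame (keys + one column per time point) from transients."""
    if not transients:
        return pd.DataFrame(columns=KEY_COLUMNS)
    times = transients[0].times
    cols = time_columns(times)
    rows = []
    for tr in transients:
        if len(tr.times) != len(times) or not np.allclose(tr.times, times):
            raise ValueError("all transients must share one time grid")
        rows.append(
            dict(genotype=tr.genotype, year=tr.year, rep=tr.rep, plant=tr.plant)
            | dict(zip(cols, tr.values))
        )
    return pd.DataFrame(rows)


def frame_to_transients(frame: pd.DataFrame) -> list[Transient]:
    """Inverse of :func:`transients_to_frame`."""
    tcols = [c for c in frame.columns if c.startswith("t_")]
    times = parse_time_columns(tcols)
    out = []
    for _, row in frame.iterrows():
        out.append(
            Transient(
                times=times,
                values=row[tcols].to_numpy(dtype=float),
                genotype=row.get("genotype"),
                year=row.get("year"),
                rep=row.get("rep"),
                plant=row.get("plant"),
            )
        )
    return out


def jip_table(
    transients: Sequence[Transient] | pd.DataFrame,
    preset: str = "extended58",
    design_plants_per_plot: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """JIP parameters for every plant, plus the plot-mean table.

    Returns ``(plant_table, plot_table)``.  Plot means average the
    plants of each (genotype, year, rep) plot; plots with fewer plants
    than the design expects are averaged over what is available, with a
    logged warning.
    """
    if isinstance(transients, pd.DataFrame):
        frame = transients
    else:
        frame = transients_to_frame(list(transients))
    names = PARAM_PRESETS[preset]
    if frame.empty:
        cols = KEY_COLUMNS + names
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=PLOT_KEYS + names)

    tcols = [c for c in frame.columns if c.startswith("t_")]
    times = parse_time_columns(tcols)
    F = frame[tcols].to_numpy(dtype=float)
    i0 = _nearest_index(times, F0_TIME, "F0")
    idx = {k: _nearest_index(times, t, k) for k, t in LANDMARK_TIMES.items()}
    i_max = np.argmax(F, axis=1)
    fm = F[np.arange(len(F)), i_max]
    # complementary area, trapezoid between t(F0) and t_Fm per row
    dt = np.diff(times)
    gap = fm[:, None] - F
    seg = 0.5 * (gap[:, :-1] + gap[:, 1:]) * dt[None, :]
    mask = (np.arange(len(dt))[None, :] >= i0) & (
        np.arange(len(dt))[None, :] < i_max[:, None]
    )
    area = (seg * mask).sum(axis=1)
    arrays = _jip_arrays(
        F[:, i0], F[:, idx["F1"]], F[:, idx["F2"]], F[:, idx["F3"]],
        F[:, idx["F4"]], F[:, idx["F5"]], fm, times[i_max], area,
    )
    plant = frame[KEY_COLUMNS].copy()
    for n in names:
        plant[n] = arrays[n]

    counts = plant.groupby(PLOT_KEYS, sort=True).size()
    expected = design_plants_per_plot
    if expected is not None and (counts < expected).any():
        short = counts[counts < expected]
        logger.warning(
            "%d plot(s) have fewer than %d plants; plot means use the "
            "available plants", len(short), expected
        )
    plot = plant.groupby(PLOT_KEYS, sort=True)[names].mean().reset_index()
    return plant, plot


def plot_mean_transients(frame: pd.DataFrame) -> pd.DataFrame:
    """Plot-level (genotype, year, rep) mean fluorescence curves."""
    tcols = [c for c in frame.columns if c.startswith("t_")]
    return frame.groupby(PLOT_KEYS, sort=True)[tcols].mean().reset_index()


class JIPTransformer:
    """Transformer-style wrapper: wide transient table -> JIP parameters.

    Follows the fit/transform protocol so it can sit in an sklearn
    pipeline ahead of a regression step; ``fit`` only records the
    parameter roster.
    """

    def __init__(self, preset: str = "extended58"):
        self.preset = preset

    def get_params(self, deep: bool = True) -> dict:
        return {"preset": self.preset}

    def set_params(self, **params) -> "JIPTransformer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "JIPTransformer":
        self.feature_names_out_ = list(PARAM_PRESETS[self.preset])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        plant, _ = jip_table(X, preset=self.preset)
        return plant[self.feature_names_out_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def read_transients_csv(path) -> pd.DataFrame:
    """Read a transient table; accepts the wide format written by the
    generator or a long (sample keys, time_s, value) format."""
    df = pd.read_csv(path, comment="#")
    if any(c.startswith("t_") for c in df.columns):
        return df
    required = {"time_s", "value"}
    if not required.issubset(df.columns):
        raise ValueError(
            "transient CSV must be wide (t_<µs> columns) or long with "
            "time_s and value columns"
        )
    keys = [c for c in KEY_COLUMNS if c in df.columns]
    wide = df.pivot_table(index=keys, columns="time_s", values="value")
    wide.columns = [f"t_{t * 1e6:.4f}" for t in wide.columns]
    return wide.reset_index()
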
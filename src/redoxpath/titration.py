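"""Spectroelectrochemical (OTTLE) titration processing and Nernstian fitting.

A redox titration records UV/Vis spectra of a protein poised at a ladder of
electrode potentials.  For a one-electron cofactor the absorbance in a band
of maximal change follows a single-transition Nernst curve

    Y(E) = a / (exp(zF(E - Em)/(RT)) + 1) + c

whose inflection point Em is the midpoint potential.  This module implements
the full reduction chain: baseline correction against a silent spectral
window, band averaging, linear drift correction anchored on a repeated
potential, min-max normalisation, nonlinear least-squares fitting of Em, and
a parametric bootstrap for its uncertainty.

Potentials are handled in mV.  Applied potentials are stored against the
reference electrode (Ag/AgCl by default) and converted to the standard
hydrogen electrode (SHE) scale with a constant offset before fitting, so all
reported midpoint potentials are vs SHE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingConfig",
    "SpectrumRecord",
    "TitrationSeries",
    "NernstFit",
    "BootstrapEstimate",
    "TitrationError",
    "FitConvergenceError",
    "read_titration",
    "write_titration",
    "baseline_correct",
    "band_average",
    "drift_correct",
    "normalize_trace",
    "to_she",
    "nernst_response",
    "fit_nernst",
    "bootstrap_em_sd",
    "process_titration",
    "determine_midpoint",
]

# Column names of the long-format titration CSV dialect.
CSV_COLUMNS = ("acquisition_index", "applied_potential_mV", "wavelength_nm", "absorbance")


class TitrationError(ValueError):
    """Raised when titration data violate a processing precondition."""


class FitConvergenceError(RuntimeError):
    """Raised when the Nernstian least-squares fit fails to converge.

    Carries the final parameter vector and residual sum of squares so the
    caller can inspect how far the optimiser got.
    """

    def __init__(self, message: str, params: tuple[float, float, float], rss: float):
        super().__init__(message)
        self.params = params
        self.rss = rss


@dataclass(frozen=True)
class ProcessingConfig:
    """Physical constants and processing windows for a titration analysis.

    Attributes
    ----------
    baseline_window : (low, high) in nm, inclusive.  The spectrum is assumed
        featureless here; its mean absorbance is subtracted per spectrum.
    analysis_band : (low, high) in nm, inclusive.  The band of maximal
        redox-linked absorbance change that is averaged into the trace.
    faraday : Faraday constant, J mol^-1 V^-1.
    gas_constant : ideal gas constant, J mol^-1 K^-1.
    temperature : K.
    electrons_z : number of electrons in the transition (held fixed in fits).
    reference_offset : mV added to applied potentials to convert the
        reference-electrode scale to SHE (Ag/AgCl ink in 100 mM KCl: +280).
    """

    baseline_window: tuple[float, float] = (650.0, 700.0)
    analysis_band: tuple[float, float] = (465.0, 485.0)
    faraday: float = 96485.34
    gas_constant: float = 8.3145
    temperature: float = 293.0
    electrons_z: int = 1
    reference_offset: float = 280.0

    def __post_init__(self) -> None:
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ValueError("baseline_window lower bound must be < upper bound")
        if self.analysis_band[0] >= self.analysis_band[1]:
            raise ValueError("analysis_band lower bound must be < upper bound")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.electrons_z < 1:
            raise ValueError("electrons_z must be >= 1")

    @property
    def thermal_voltage_mV(self) -> float:
        """RT/(zF) in mV — the natural width scale of the transition."""
        return 1000.0 * self.gas_constant * self.temperature / (self.electrons_z * self.faraday)


@dataclass
class SpectrumRecord:
    """One spectrum at one poised potential.

    ``applied_potential`` is in mV against the reference electrode;
    ``acquisition_index`` records the order of measurement (0-based) and is
    the abscissa of the drift correction.
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    applied_potential: float
    acquisition_index: int

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.shape != self.absorbances.shape:
            raise TitrationError("wavelengths and absorbances must have equal length")
        if self.wavelengths.size < 2 or np.any(np.diff(self.wavelengths) <= 0):
            raise TitrationError(
                f"wavelengths must be strictly increasing "
                f"(acquisition_index={self.acquisition_index})"
            )
        if not np.all(np.isfinite(self.absorbances)):
            raise TitrationError(
                f"non-finite absorbance in spectrum {self.acquisition_index}"
            )
        if self.acquisition_index < 0:
            raise TitrationError("acquisition_index must be >= 0")


@dataclass
class TitrationSeries:
    """An ordered series of spectra from one titration run."""

    spectra: list[SpectrumRecord]
    reference_offset: float = 280.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = sorted(self.spectra, key=lambda s: s.acquisition_index)
        indices = [s.acquisition_index for s in self.spectra]
        if indices != list(range(len(indices))):
            raise TitrationError(
                f"acquisition_index values must be unique and contiguous from 0, got {indices}"
            )

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class NernstFit:
    """Result of a single-transition Nernstian fit (potentials vs SHE)."""

    Em: float
    amplitude_a: float
    offset_c: float
    residual_sum_squares: float
    n_points: int
    em_in_range: bool = True


@dataclass
class BootstrapEstimate:
    """Parametric-bootstrap summary of the midpoint-potential distribution."""

    Em_mean: float
    Em_sd: float
    n_replicates: int
    sd_scale: float
    seed: int
    n_failed: int = 0


# ---------------------------------------------------------------------------
# I/O — the long-format titration CSV dialect
# ---------------------------------------------------------------------------

def read_titration(source: str | Path, reference_offset: float | None = None) -> TitrationSeries:
    """Read a titration series from the long-format CSV dialect.

    The file has columns ``acquisition_index, applied_potential_mV,
    wavelength_nm, absorbance`` (one row per spectrum sample) and may carry
    an optional header comment ``# reference_offset_mV=<float>``.  An
    explicit ``reference_offset`` argument overrides the header.
    """
    source = Path(source)
    header_offset = None
    with open(source) as fh:
        first = fh.readline()
    if first.startswith("#"):
        key, _, val = first.lstrip("#").strip().partition("=")
        if key.strip() == "reference_offset_mV":
            try:
                header_offset = float(val)
            except ValueError as exc:
                raise TitrationError(f"unparseable reference_offset_mV header: {first!r}") from exc

    df = pd.read_csv(source, comment="#")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise TitrationError(f"missing columns {sorted(missing)} in {source}")
    bad = df[df[list(CSV_COLUMNS)].isna().any(axis=1)]
    if len(bad):
        raise TitrationError(f"ragged/missing values at data row {bad.index[0]} of {source}")

    spectra = []
    for idx, grp in df.groupby("acquisition_index", sort=True):
        potentials = grp["applied_potential_mV"].unique()
        if len(potentials) > 1:
            raise TitrationError(
                f"duplicated acquisition_index {idx}: conflicting potentials {potentials.tolist()}"
            )
        grp = grp.sort_values("wavelength_nm")
        wl = grp["wavelength_nm"].to_numpy()
        if np.any(np.diff(wl) <= 0):
            raise TitrationError(f"non-monotone or duplicated wavelengths in spectrum {idx}")
        spectra.append(
            SpectrumRecord(
                wavelengths=wl,
                absorbances=grp["absorbance"].to_numpy(),
                applied_potential=float(potentials[0]),
                acquisition_index=int(idx),
            )
        )

    offset = reference_offset if reference_offset is not None else (
        header_offset if header_offset is not None else 280.0
    )
    return TitrationSeries(spectra=spectra, reference_offset=offset, metadata={"source": str(source)})


def write_titration(series: TitrationSeries, path: str | Path) -> Path:
    """Write a series in the long CSV dialect (inverse of :func:`read_titration`)."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "acquisition_index": s.acquisition_index,
                "applied_potential_mV": s.applied_potential,
                "wavelength_nm": s.wavelengths,
                "absorbance": s.absorbances,
            }
        )
        for s in series.spectra
    ]
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# reference_offset_mV={series.reference_offset}\n")
        df.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# Spectral processing
# ---------------------------------------------------------------------------

def _window_mask(wavelengths: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    # inclusive membership on the recorded grid; no interpolation
    return (wavelengths >= window[0]) & (wavelengths <= window[1])


def baseline_correct(series: TitrationSeries, config: ProcessingConfig | None = None) -> TitrationSeries:
    """Subtract, per spectrum, the mean absorbance over the baseline window.

    The 650–700 nm region carries no redox-linked signal for these proteins,
    so its mean estimates the flat instrumental offset of each spectrum.
    Idempotent: the corrected spectra average exactly to zero in the window.
    """
    config = config or ProcessingConfig()
    corrected = []
    for s in series.spectra:
        mask = _window_mask(s.wavelengths, config.baseline_window)
        if mask.sum() < 2:
            raise TitrationError(
                f"spectrum {s.acquisition_index}: fewer than 2 samples in baseline window "
                f"{config.baseline_window}"
            )
        corrected.append(
            replace(s, absorbances=s.absorbances - s.absorbances[mask].mean())
        )
    return TitrationSeries(
        spectra=corrected, reference_offset=series.reference_offset, metadata=dict(series.metadata)
    )


def band_average(series: TitrationSeries, config: ProcessingConfig | None = None) -> pd.DataFrame:
    """Average each spectrum over the analysis band into a scalar trace.

    Returns a DataFrame with columns ``acquisition_index``,
    ``applied_potential`` (reference-electrode scale) and ``value``, ordered
    by acquisition.
    """
    config = config or ProcessingConfig()
    rows = []
    for s in series.spectra:
        mask = _window_mask(s.wavelengths, config.analysis_band)
        if mask.sum() < 1:
            raise TitrationError(
                f"spectrum {s.acquisition_index}: no samples in analysis band "
                f"{config.analysis_band}"
            )
        rows.append(
            {
                "acquisition_index": s.acquisition_index,
                "applied_potential": s.applied_potential,
                "value": float(s.absorbances[mask].mean()),
            }
        )
    return pd.DataFrame(rows).sort_values("acquisition_index", ignore_index=True)


def drift_correct(trace: pd.DataFrame, repeated_potential: float) -> pd.DataFrame:
    """Remove a linear-in-acquisition-index drift from a band trace.

    The thin-layer cell's optical path length can shrink during the run, so
    the same potential measured first and last should — but does not — give
    the same band absorbance.  A ramp linear in acquisition index, anchored
    so those two entries become equal, is subtracted from every entry.
    """
    trace = trace.sort_values("acquisition_index", ignore_index=True)
    at = np.isclose(trace["applied_potential"], repeated_potential, atol=1e-6)
    if at.sum() < 2:
        raise TitrationError(
            f"potential {repeated_potential} mV appears {int(at.sum())} time(s); "
            "need a first and a last measurement at the same potential — skip drift correction"
        )
    idx = trace.index[at]
    i0, i1 = int(idx[0]), int(idx[-1])
    x0 = float(trace.loc[i0, "acquisition_index"])
    x1 = float(trace.loc[i1, "acquisition_index"])
    d = float(trace.loc[i1, "value"] - trace.loc[i0, "value"])
    ramp = d * (trace["acquisition_index"] - x0) / (x1 - x0)
    out = trace.copy()
    out["value"] = trace["value"] - ramp
    return out


def normalize_trace(trace: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale the trace to [0, 1], then re-zero at the lowest potential.

    The most-reduced spectrum (lowest applied potential) serves as the
    reference A_red, so the returned values are Y = A − A_red on a
    normalised scale.  For the usual orientation (absorbance grows on
    oxidation) this leaves the trace in [0, 1] starting at 0; a decreasing
    trace ends up in [−1, 0].  Em is invariant to this affine choice.
    Idempotent.  A constant trace carries no transition and is rejected.
    """
    values = trace["value"].to_numpy(dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax - vmin <= 0 or not np.isfinite(vmax - vmin):
        raise TitrationError("constant trace: no redox transition present")
    scaled = (values - vmin) / (vmax - vmin)
    ref = scaled[int(np.argmin(trace["applied_potential"].to_numpy()))]
    out = trace.copy()
    out["value"] = scaled - ref
    return out


def to_she(applied_potential, config: ProcessingConfig | None = None):
    """Convert reference-electrode potentials (mV) to the SHE scale."""
    config = config or ProcessingConfig()
    return np.asarray(applied_potential, dtype=float) + config.reference_offset


# ---------------------------------------------------------------------------
# Nernstian model and fitting
# ---------------------------------------------------------------------------

def nernst_response(E, Em: float, a: float, c: float, config: ProcessingConfig | None = None):
    """Single-transition Nernst curve Y = a/(exp(zF(E−Em)/RT) + 1) + c.

    ``E`` and ``Em`` in mV on the same scale.  Monotone in E, with limits
    a + c (E → −∞) and c (E → +∞); at E = Em the value is a/2 + c.
    """
    config = config or ProcessingConfig()
    x = (np.asarray(E, dtype=float) - Em) / config.thermal_voltage_mV
    return a / (np.exp(np.clip(x, -500.0, 500.0)) + 1.0) + c


def _linear_amplitudes(E: np.ndarray, y: np.ndarray, Em_grid: np.ndarray,
                       config: ProcessingConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best (a, c) and RSS for each candidate Em, by linear least squares.

    For fixed Em the model is linear in (a, c); the 2x2 normal equations are
    solved in closed form, vectorised over the whole Em grid.
    """
    x = (E[None, :] - Em_grid[:, None]) / config.thermal_voltage_mV
    f = 1.0 / (np.exp(np.clip(x, -500.0, 500.0)) + 1.0)  # (n_grid, n_pts)
    n = E.size
    sf = f.sum(axis=1)
    sff = (f * f).sum(axis=1)
    sy = y.sum()
    sfy = (f * y[None, :]).sum(axis=1)
    det = n * sff - sf * sf
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    a = (n * sfy - sf * sy) / det
    c = (sy - a * sf) / n
    resid = a[:, None] * f + c[:, None] - y[None, :]
    rss = (resid * resid).sum(axis=1)
    return a, c, rss


def fit_nernst(
    potentials_SHE: Sequence[float],
    values: Sequence[float],
    config: ProcessingConfig | None = None,
    initial: tuple[float, float, float] | None = None,
) -> NernstFit:
    """Fit the single-transition Nernst curve by least squares.

    The electron count z is held fixed at ``config.electrons_z``; amplitude
    ``a`` is unconstrained in sign so one functional form covers traces that
    rise or fall with potential.  Initialisation scans a coarse Em grid with
    closed-form (a, c) at each candidate, then a trust-region least-squares
    refinement polishes all three parameters.  ``initial`` skips the scan
    (used by the bootstrap, which starts from the point-estimate fit).
    """
    config = config or ProcessingConfig()
    E = np.asarray(potentials_SHE, dtype=float)
    y = np.asarray(values, dtype=float)
    if E.size != y.size:
        raise TitrationError("potentials and values must have equal length")
    if np.unique(E).size < 4:
        raise TitrationError("need at least 4 distinct potentials to fit")
    span = E.max() - E.min()
    if span <= 2 * config.thermal_voltage_mV:
        raise TitrationError(
            f"potential span {span:.1f} mV too narrow (need > 2·RT/zF = "
            f"{2 * config.thermal_voltage_mV:.1f} mV)"
        )

    if initial is None:
        margin = 2 * config.thermal_voltage_mV
        grid = np.arange(E.min() - margin, E.max() + margin + 1.0, 1.0)
        a_g, c_g, rss_g = _linear_amplitudes(E, y, grid, config)
        best = int(np.nanargmin(rss_g))
        p0 = np.array([grid[best], a_g[best], c_g[best]])
    else:
        p0 = np.asarray(initial, dtype=float)

    vt = config.thermal_voltage_mV

    def resid(p):
        x = (E - p[0]) / vt
        return p[1] / (np.exp(np.clip(x, -500.0, 500.0)) + 1.0) + p[2] - y

    res = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    rss = float(res.cost * 2)
    if not res.success:
        raise FitConvergenceError(
            f"Nernst fit did not converge: {res.message}", tuple(res.x), rss
        )
    Em, a, c = (float(v) for v in res.x)
    in_range = bool(E.min() <= Em <= E.max())
    if not in_range:
        logger.warning("fitted Em = %.1f mV lies outside the sampled range [%.0f, %.0f]",
                       Em, E.min(), E.max())
    return NernstFit(Em=Em, amplitude_a=a, offset_c=c,
                     residual_sum_squares=rss, n_points=int(E.size), em_in_range=in_range)


def bootstrap_em_sd(
    potentials: Sequence[float],
    means: Sequence[float],
    sds: Sequence[float],
    config: ProcessingConfig | None = None,
    n_replicates: int = 1000,
    sd_scale: float = 3.0,
    seed: int = 0,
) -> BootstrapEstimate:
    """Parametric bootstrap of the midpoint potential.

    Synthetic datasets are drawn from per-point Gaussians centred on the
    experimental means with standard deviations ``sd_scale`` times the
    experimental ones (the ×3 inflation makes the estimate deliberately
    conservative), each is refit, and the SD of the resulting Em
    distribution is the reported uncertainty.  Replicates whose refit fails
    are dropped and counted; more than 10 % failures aborts.
    """
    config = config or ProcessingConfig()
    E = np.asarray(potentials, dtype=float)
    mu = np.asarray(means, dtype=float)
    sd = np.asarray(sds, dtype=float)
    if not (E.size == mu.size == sd.size):
        raise TitrationError("potentials, means and sds must have equal length")
    if np.any(sd < 0):
        raise TitrationError("standard deviations must be non-negative")
    if n_replicates < 2:
        raise TitrationError("need at least 2 bootstrap replicates")

    base = fit_nernst(E, mu, config)
    init = (base.Em, base.amplitude_a, base.offset_c)
    rng = np.random.default_rng(seed)
    ems = []
    n_failed = 0
    for _ in range(n_replicates):
        y = mu + rng.normal(size=mu.size) * (sd_scale * sd)
        try:
            ems.append(fit_nernst(E, y, config, initial=init).Em)
        except (FitConvergenceError, TitrationError):
            n_failed += 1
    if n_failed > 0.10 * n_replicates:
        raise FitConvergenceError(
            f"{n_failed}/{n_replicates} bootstrap refits failed (> 10 %)", init, base.residual_sum_squares
        )
    ems_arr = np.asarray(ems)
    sd_em = float(ems_arr.std(ddof=1)) if ems_arr.size > 1 else 0.0
    return BootstrapEstimate(
        Em_mean=float(ems_arr.mean()), Em_sd=sd_em,
        n_replicates=n_replicates, sd_scale=sd_scale, seed=seed, n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def process_titration(
    series: TitrationSeries,
    config: ProcessingConfig | None = None,
    repeated_potential: float | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Run baseline → band average → (drift) → (normalise) on one series."""
    config = config or ProcessingConfig()
    trace = band_average(baseline_correct(series, config), config)
    if repeated_potential is not None:
        trace = drift_correct(trace, repeated_potential)
    if normalize:
        trace = normalize_trace(trace)
    return trace


def _split_branches(trace: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a trace at the extremal potential into two monotone branches."""
    trace = trace.sort_values("acquisition_index", ignore_index=True)
    pot = trace["applied_potential"].to_numpy()
    # an oxidising sweep turns at the maximum potential, a reducing one at the minimum
    turn = int(np.argmax(pot)) if pot[0] < pot.mean() else int(np.argmin(pot))
    return trace.iloc[: turn + 1], trace.iloc[turn:]


def determine_midpoint(
    series_list: Iterable[TitrationSeries],
    config: ProcessingConfig | None = None,
    repeated_potential: float | None = None,
    branch_mode: str = "joint",
    n_bootstrap: int = 1000,
    sd_scale: float = 3.0,
    seed: int = 0,
    label: str = "",
) -> dict:
    """Full analysis of replicate titrations: pipeline, fit, bootstrap.

    Each replicate series is processed independently; per-potential means and
    SDs across replicates are then fitted (the SDs feed the parametric
    bootstrap).  With ``branch_mode='split'`` the oxidising and reducing
    sweep halves are additionally fitted separately and their Em difference
    reported as hysteresis.

    Returns a JSON-ready report dict.
    """
    config = config or ProcessingConfig()
    series_list = list(series_list)
    if not series_list:
        raise TitrationError("no titration series supplied")
    traces = [
        process_titration(s, config, repeated_potential=repeated_potential)
        for s in series_list
    ]
    pooled = pd.concat(traces, ignore_index=True)
    grouped = pooled.groupby("applied_potential")["value"].agg(["mean", "std", "count"])
    grouped["std"] = grouped["std"].fillna(0.0)
    potentials_she = to_she(grouped.index.to_numpy(), config)
    fit = fit_nernst(potentials_she, grouped["mean"].to_numpy(), config)
    boot = bootstrap_em_sd(
        potentials_she, grouped["mean"].to_numpy(), grouped["std"].to_numpy(),
        config, n_replicates=n_bootstrap, sd_scale=sd_scale, seed=seed,
    )
    report = {
        "protein_label": label,
        "Em_mV_SHE": fit.Em,
        "Em_sd_mV": boot.Em_sd,
        "a": fit.amplitude_a,
        "c": fit.offset_c,
        "n_points": fit.n_points,
        "branch_mode": branch_mode,
        "seed": seed,
        "em_in_sampled_range": fit.em_in_range,
        "bootstrap_n_failed": boot.n_failed,
    }
    if branch_mode == "split":
        fits = []
        for part in range(2):
            pts = pd.concat([_split_branches(t)[part] for t in traces], ignore_index=True)
            fits.append(fit_nernst(to_she(pts["applied_potential"].to_numpy(), config),
                                   pts["value"].to_numpy(), config))
        report["Em_branch_1_mV_SHE"] = fits[0].Em
        report["Em_branch_2_mV_SHE"] = fits[1].Em
        report["hysteresis_mV"] = fits[1].Em - fits[0].Em
    return report


def save_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2) + "\n")
    return path
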
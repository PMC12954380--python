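"""Synthetic titration datasets and toy cofactor structures.

The generator emulates the statistical structure of an OTTLE redox
titration: reduced and oxidised component spectra (Gaussian-band
caricatures of real difference spectra, with extra oxidised absorbance in
the 420–580 nm region), one-electron Nernstian mixing over a potential
ladder, triplicate runs, i.i.d. Gaussian measurement noise, and a
multiplicative path-length drift that shrinks linearly across acquisition
order.  It also writes minimal PDB files with cofactor heterogroups at
chosen centroids, for exercising the geometry module without downloading
deposited structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .titration import (
    ProcessingConfig,
    SpectrumRecord,
    TitrationSeries,
    write_titration,
)

__all__ = [
    "ComponentSpectra",
    "TitrationTruth",
    "default_ladder",
    "make_component_spectra",
    "oxidized_fraction",
    "simulate_titration",
    "make_toy_structure",
    "COFACTOR_TEMPLATES",
    "template_atom_count",
]


@dataclass
class ComponentSpectra:
    """Pure reduced / oxidised absorbance spectra on a shared grid (nm, AU)."""

    wavelengths: np.ndarray
    reduced: np.ndarray
    oxidized: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reduced = np.asarray(self.reduced, dtype=float)
        self.oxidized = np.asarray(self.oxidized, dtype=float)
        if not (self.wavelengths.shape == self.reduced.shape == self.oxidized.shape):
            raise ValueError("component spectra must share one wavelength grid")


@dataclass
class TitrationTruth:
    """Ground-truth parameters of a simulated titration.

    ``ladder`` lists the applied potentials in acquisition order, in mV vs
    SHE; the default sweeps −50 to +550 mV in 20 mV steps and repeats the
    first potential at the end so the drift correction has its anchor pair.
    ``noise_sd`` is the per-sample Gaussian noise (AU); ``drift_total`` the
    total fractional path-length loss over the run.
    """

    Em_true: float
    noise_sd: float = 0.02
    drift_total: float = 0.0
    ladder: list[float] = field(default_factory=lambda: default_ladder())
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = np.asarray(self.ladder, dtype=float)
        if ladder.size < 2:
            raise ValueError("ladder needs at least 2 potentials")
        steps = np.abs(np.diff(ladder))
        # the trailing return-to-start jump (drift anchor) is exempt
        sweep = steps[:-1] if np.isclose(ladder[-1], ladder[0]) and ladder.size > 2 else steps
        if sweep.size and (sweep.min() < 20 - 1e-9 or sweep.max() > 50 + 1e-9):
            raise ValueError("ladder sweep steps must lie within 20-50 mV")


def default_ladder(
    start: float = -50.0, stop: float = 550.0, step: float = 20.0,
    repeat_first_at_end: bool = True,
) -> list[float]:
    """Potential ladder in mV vs SHE, optionally re-measuring the start."""
    ladder = list(np.arange(start, stop + step / 2, step))
    if repeat_first_at_end:
        ladder.append(ladder[0])
    return ladder


DEFAULT_GRID = np.arange(250.0, 800.0 + 0.25, 0.5)

# (center nm, width nm, height AU) Gaussian bands; the oxidised state gains
# absorbance in the 320-380 and 420-580 nm regions, the reduced state keeps
# a weak broad band so both states are non-trivial.
DEFAULT_OXIDIZED_PEAKS = [(350.0, 25.0, 0.6), (475.0, 40.0, 0.8), (560.0, 30.0, 0.2)]
DEFAULT_REDUCED_PEAKS = [(420.0, 30.0, 0.3)]


def make_component_spectra(
    oxidized_peaks: Sequence[tuple[float, float, float]] | None = None,
    reduced_peaks: Sequence[tuple[float, float, float]] | None = None,
    wavelengths: np.ndarray | None = None,
    flat_offset: float = 0.05,
) -> ComponentSpectra:
    """Build component spectra as sums of Gaussian bands plus a flat offset.

    The grid must cover both the analysis band (465–485 nm) and the
    baseline window (650–700 nm); with the default peaks the oxidised state
    absorbs more than the reduced state throughout the analysis band, so the
    band trace carries the redox signal the pipeline expects.
    """
    if oxidized_peaks is None:
        oxidized_peaks = DEFAULT_OXIDIZED_PEAKS
    if reduced_peaks is None:
        reduced_peaks = DEFAULT_REDUCED_PEAKS
    wl = DEFAULT_GRID.copy() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if wl.min() > 465.0 or wl.max() < 700.0:
        raise ValueError("wavelength grid must cover 465-485 nm and 650-700 nm")

    def bands(peaks):
        out = np.full_like(wl, flat_offset)
        for center, width, height in peaks:
            if width <= 0:
                raise ValueError(f"peak width must be positive, got {width}")
            out = out + height * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return out

    return ComponentSpectra(wavelengths=wl, reduced=bands(reduced_peaks), oxidized=bands(oxidized_peaks))


def oxidized_fraction(E, Em: float, config: ProcessingConfig | None = None):
    """Equilibrium oxidised fraction 1/(1 + exp(−zF(E−Em)/RT)); complements
    the reduced fraction exactly."""
    config = config or ProcessingConfig()
    x = (np.asarray(E, dtype=float) - Em) / config.thermal_voltage_mV
    return 1.0 / (1.0 + np.exp(np.clip(-x, -500.0, 500.0)))


def simulate_titration(
    truth: TitrationTruth,
    components: ComponentSpectra | None = None,
    config: ProcessingConfig | None = None,
    baseline_offset: float = 0.1,
    out_dir: str | Path | None = None,
) -> list[TitrationSeries]:
    """Simulate replicate titration series from ground truth.

    Each spectrum is the Nernstian mixture of the component spectra plus a
    flat baseline offset, scaled by a path factor (1 − drift_total·i/(N−1))
    that emulates the thin-layer cell losing path length across the run,
    plus i.i.d. Gaussian noise.  Applied potentials are written on the
    reference-electrode scale (ladder vs SHE minus the reference offset).

    With ``out_dir`` set, writes ``replicate_<k>.csv`` in the titration CSV
    dialect plus a ``truth.json`` record; output is byte-identical under a
    fixed seed.
    """
    config = config or ProcessingConfig()
    components = components or make_component_spectra()
    ladder = np.asarray(truth.ladder, dtype=float)
    if truth.drift_total != 0.0 and not np.isclose(ladder[0], ladder[-1]):
        raise ValueError(
            "drift simulation needs the first potential repeated at the end "
            "so the drift correction can be anchored"
        )
    rng = np.random.default_rng(truth.seed)
    n = ladder.size
    series_list = []
    for rep in range(truth.replicates):
        spectra = []
        for i, E_she in enumerate(ladder):
            f_ox = oxidized_fraction(E_she, truth.Em_true, config)
            pure = baseline_offset + (1.0 - f_ox) * components.reduced + f_ox * components.oxidized
            path = 1.0 - truth.drift_total * (i / (n - 1) if n > 1 else 0.0)
            absorbance = pure * path + rng.normal(size=pure.size) * truth.noise_sd
            spectra.append(
                SpectrumRecord(
                    wavelengths=components.wavelengths,
                    absorbances=absorbance,
                    applied_potential=float(E_she - config.reference_offset),
                    acquisition_index=i,
                )
            )
        series_list.append(
            TitrationSeries(
                spectra=spectra,
                reference_offset=config.reference_offset,
                metadata={"replicate": rep, "Em_true": truth.Em_true},
            )
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep, series in enumerate(series_list):
            write_titration(series, out_dir / f"replicate_{rep}.csv")
        truth_record = {
            "Em_true_mV_SHE": truth.Em_true,
            "noise_sd_AU": truth.noise_sd,
            "drift_total_fraction": truth.drift_total,
            "ladder_mV_SHE": [float(v) for v in ladder],
            "replicates": truth.replicates,
            "seed": truth.seed,
            "reference_offset_mV": config.reference_offset,
        }
        (out_dir / "truth.json").write_text(json.dumps(truth_record, indent=2) + "\n")
    return series_list


# ---------------------------------------------------------------------------
# Toy structures for the geometry module
# ---------------------------------------------------------------------------

# Rigid heavy-atom templates (atom name, element, xyz offset in Å from the
# centroid), deliberately minimal: enough atoms to give each cofactor a
# finite extent and the right identifying composition.
COFACTOR_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    # [2Fe2S] rhombus
    "FES": [
        ("FE1", "Fe", (-1.35, 0.0, 0.0)),
        ("FE2", "Fe", (1.35, 0.0, 0.0)),
        ("S1", "S", (0.0, 1.1, 0.0)),
        ("S2", "S", (0.0, -1.1, 0.0)),
    ],
    # [4Fe4S] cubane
    "SF4": [
        ("FE1", "Fe", (1.0, 1.0, 1.0)),
        ("FE2", "Fe", (-1.0, -1.0, 1.0)),
        ("FE3", "Fe", (-1.0, 1.0, -1.0)),
        ("FE4", "Fe", (1.0, -1.0, -1.0)),
        ("S1", "S", (-1.0, 1.0, 1.0)),
        ("S2", "S", (1.0, -1.0, 1.0)),
        ("S3", "S", (1.0, 1.0, -1.0)),
        ("S4", "S", (-1.0, -1.0, -1.0)),
    ],
    # [3Fe4S]: cubane minus one iron
    "F3S": [
        ("FE1", "Fe", (1.0, 1.0, 1.0)),
        ("FE3", "Fe", (-1.0, 1.0, -1.0)),
        ("FE4", "Fe", (1.0, -1.0, -1.0)),
        ("S1", "S", (-1.0, 1.0, 1.0)),
        ("S2", "S", (1.0, -1.0, 1.0)),
        ("S3", "S", (1.0, 1.0, -1.0)),
        ("S4", "S", (-1.0, -1.0, -1.0)),
    ],
    # b-type heme: iron, pyrrole nitrogens, meso carbons
    "HEM": [
        ("FE", "Fe", (0.0, 0.0, 0.0)),
        ("NA", "N", (2.0, 0.0, 0.0)),
        ("NB", "N", (0.0, 2.0, 0.0)),
        ("NC", "N", (-2.0, 0.0, 0.0)),
        ("ND", "N", (0.0, -2.0, 0.0)),
        ("CHA", "C", (2.4, 2.4, 0.0)),
        ("CHB", "C", (-2.4, 2.4, 0.0)),
        ("CHC", "C", (-2.4, -2.4, 0.0)),
        ("CHD", "C", (2.4, -2.4, 0.0)),
    ],
    # FAD: isoalloxazine fragment
    "FAD": [
        ("N5", "N", (0.0, 0.7, 0.0)),
        ("N10", "N", (0.0, -0.7, 0.0)),
        ("C4X", "C", (1.2, 1.4, 0.0)),
        ("C10", "C", (1.2, -1.4, 0.0)),
        ("C5X", "C", (-1.2, 1.4, 0.0)),
        ("C9A", "C", (-1.2, -1.4, 0.0)),
    ],
    # NADP: nicotinamide fragment
    "NAP": [
        ("N1N", "N", (0.0, 0.0, 0.0)),
        ("C2N", "C", (1.2, 0.7, 0.0)),
        ("C3N", "C", (1.2, 2.1, 0.0)),
        ("C4N", "C", (0.0, 2.8, 0.0)),
        ("C5N", "C", (-1.2, 2.1, 0.0)),
        ("C6N", "C", (-1.2, 0.7, 0.0)),
        ("C7N", "C", (2.5, 2.8, 0.0)),
    ],
}
COFACTOR_TEMPLATES["HEC"] = COFACTOR_TEMPLATES["HEM"]
COFACTOR_TEMPLATES["NDP"] = COFACTOR_TEMPLATES["NAP"]


def template_atom_count(kind: str) -> int:
    return len(COFACTOR_TEMPLATES[kind])


def make_toy_structure(
    layout: Sequence[tuple[str, tuple[float, float, float]]],
    out_path: str | Path | None = None,
) -> gemmi.Structure:
    """Build a minimal structure with cofactor heterogroups at given centroids.

    ``layout`` is a list of (residue code, (x, y, z) Å) pairs; codes come
    from :data:`COFACTOR_TEMPLATES` (HEM, HEC, FES, SF4, F3S, FAD, NAP).
    Each cofactor becomes one HETATM residue on chain X with its rigid
    template geometry translated to the centroid.  Writes PDB if
    ``out_path`` is given.
    """
    st = gemmi.Structure()
    st.name = "toy_cofactors"
    model = gemmi.Model("1")
    chain = gemmi.Chain("X")
    serial = 1
    for seq, (kind, centroid) in enumerate(layout, start=1):
        kind = kind.upper()
        if kind not in COFACTOR_TEMPLATES:
            raise ValueError(f"unknown cofactor kind {kind!r}; known: {sorted(COFACTOR_TEMPLATES)}")
        res = gemmi.Residue()
        res.name = kind
        res.seqid = gemmi.SeqId(seq, " ")
        res.het_flag = "H"
        cx, cy, cz = (float(v) for v in centroid)
        for name, element, (dx, dy, dz) in COFACTOR_TEMPLATES[kind]:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(cx + dx, cy + dy, cz + dz)
            atom.occ = 1.0
            atom.b_iso = 20.0
            atom.serial = serial
            serial += 1
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if out_path is not None:
        st.write_pdb(str(out_path))
    return st
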
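"""Electron-bifurcation energetics bookkeeping.

A Rieske/cytochrome *b* complex oxidises a quinol and bifurcates the two
electrons: one runs downhill through the Rieske [2Fe2S] cluster to a
high-potential acceptor, the other runs uphill through the *b*-type hemes
to a low-potential acceptor.  Whether the overall cycle is thermodynamically
feasible is pure redox-potential arithmetic on the half-reaction midpoint
potentials (E°′, mV vs SHE):

* driving force of the favorable branch  = E(acceptor) − E(quinone)
* uphill requirement of the other branch = E(quinone) − E(acceptor)
* net = favorable − required; feasible when net ≥ 0.

Two empirical regularities of this protein family are also encoded: the
Rieske cluster and the positive-side heme b_P sit symmetrically around the
quinone potential (so b_P ≈ 2·E(quinone) − E(Rieske)), and the
negative-side heme b_N sits ~130 mV above b_P.

For the anammox bacterium *Kuenenia stuttgartiensis* the relevant couples
are menaquinone-7 (−70 mV), NAD(P)+/NAD(P)H (−320 mV) and nitrite/NO
(+380 mV), with experimentally determined Rieske potentials of 303 mV
(Kuste4569) and 335 mV (Kustd1480).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "RedoxCouple",
    "BifurcationScheme",
    "EnergeticsReport",
    "DEFAULT_COUPLES",
    "FARADAY",
    "driving_force",
    "uphill_requirement",
    "estimate_bp",
    "estimate_bn",
    "assess_scheme",
    "potential_to_energy",
    "read_couples",
    "format_report",
]

FARADAY = 96485.34  # J mol^-1 V^-1


@dataclass(frozen=True)
class RedoxCouple:
    """A named half-reaction with midpoint potential in mV vs SHE."""

    name: str
    Em: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.Em == self.Em and abs(self.Em) != float("inf")):
            raise ValueError(f"non-finite Em for couple {self.name!r}")


DEFAULT_COUPLES: dict[str, RedoxCouple] = {
    c.name: c
    for c in [
        RedoxCouple("MK7", -70.0, "menaquinone-7, dominant K. stuttgartiensis quinone"),
        RedoxCouple("NADP", -320.0, "NAD(P)+/NAD(P)H"),
        RedoxCouple("nitrite_NO", 380.0, "NO2-/NO"),
        RedoxCouple("Kuste4569", 303.0, "Rieske [2Fe2S], spectroelectrochemistry"),
        RedoxCouple("Kustd1480", 335.0, "Rieske [2Fe2S], spectroelectrochemistry"),
    ]
}


def _em(x: "RedoxCouple | float") -> float:
    return x.Em if isinstance(x, RedoxCouple) else float(x)


def driving_force(donor: "RedoxCouple | float", acceptor: "RedoxCouple | float") -> float:
    """E(acceptor) − E(donor) in mV; positive = thermodynamically favorable."""
    return _em(acceptor) - _em(donor)


def uphill_requirement(donor: "RedoxCouple | float", acceptor: "RedoxCouple | float") -> float:
    """E(donor) − E(acceptor) in mV; positive when the transfer is uphill.

    Exactly the negative of :func:`driving_force`.
    """
    return -driving_force(donor, acceptor)


def estimate_bp(quinone: "RedoxCouple | float", rieske: "RedoxCouple | float") -> float:
    """Heme b_P potential from quinol symmetry: 2·E(quinone) − E(Rieske).

    The unique value placing Rieske and b_P symmetrically around the
    quinone potential.
    """
    return 2.0 * _em(quinone) - _em(rieske)


def estimate_bn(bp_Em: float, offset: float = 130.0) -> float:
    """Heme b_N potential from the ~130 mV b_P → b_N family trend."""
    return bp_Em + offset


@dataclass(frozen=True)
class BifurcationScheme:
    """The four couples of a bifurcation cycle plus the b_P→b_N trend offset."""

    quinone: RedoxCouple
    rieske: RedoxCouple
    high_branch_acceptor: RedoxCouple
    low_branch_acceptor: RedoxCouple
    bp_offset_to_bn: float = 130.0


@dataclass(frozen=True)
class EnergeticsReport:
    favorable_mV: float
    required_mV: float
    net_mV: float
    bp_estimate_mV: float
    bn_estimate_mV: float
    feasible: bool

    def to_dict(self) -> dict:
        return {
            "favorable_mV": self.favorable_mV,
            "required_mV": self.required_mV,
            "net_mV": self.net_mV,
            "bp_estimate_mV": self.bp_estimate_mV,
            "bn_estimate_mV": self.bn_estimate_mV,
            "feasible": self.feasible,
        }


def assess_scheme(scheme: BifurcationScheme) -> EnergeticsReport:
    """Evaluate the full bifurcation ledger for a scheme.

    favorable = driving force quinone → high-branch acceptor;
    required = uphill requirement quinone → low-branch acceptor;
    net = favorable − required, feasible when net ≥ 0.
    """
    favorable = driving_force(scheme.quinone, scheme.high_branch_acceptor)
    required = uphill_requirement(scheme.quinone, scheme.low_branch_acceptor)
    bp = estimate_bp(scheme.quinone, scheme.rieske)
    return EnergeticsReport(
        favorable_mV=favorable,
        required_mV=required,
        net_mV=favorable - required,
        bp_estimate_mV=bp,
        bn_estimate_mV=estimate_bn(bp, scheme.bp_offset_to_bn),
        feasible=(favorable - required) >= 0,
    )


def potential_to_energy(delta_mV: float, n_electrons: int = 1) -> float:
    """Free energy of moving n electrons through ΔE: ΔG = −nFΔE, in kJ/mol."""
    return -n_electrons * FARADAY * (delta_mV / 1000.0) / 1000.0


def read_couples(path: str | Path) -> dict[str, RedoxCouple]:
    """Read a couples table CSV with columns name, Em_mV[, source]."""
    df = pd.read_csv(path, comment="#")
    if "name" not in df.columns or "Em_mV" not in df.columns:
        raise ValueError(f"couples table {path} needs columns name, Em_mV")
    couples = {}
    for _, row in df.iterrows():
        name = str(row["name"]).strip()
        if name in couples:
            raise ValueError(f"duplicate couple name {name!r} in {path}")
        couples[name] = RedoxCouple(
            name=name, Em=float(row["Em_mV"]),
            source=str(row.get("source", "") or ""),
        )
    return couples


def format_report(scheme: BifurcationScheme, report: EnergeticsReport) -> str:
    """Human-readable ledger, one branch per block."""
    lines = [
        "Electron bifurcation ledger (mV vs SHE)",
        f"  quinone          {scheme.quinone.name:<14s} {scheme.quinone.Em:+8.1f}",
        f"  Rieske           {scheme.rieske.name:<14s} {scheme.rieske.Em:+8.1f}",
        f"  high branch  ->  {scheme.high_branch_acceptor.name:<14s} "
        f"{scheme.high_branch_acceptor.Em:+8.1f}   driving force {report.favorable_mV:+8.1f}",
        f"  low branch   ->  {scheme.low_branch_acceptor.name:<14s} "
        f"{scheme.low_branch_acceptor.Em:+8.1f}   uphill need   {report.required_mV:+8.1f}",
        f"  net                                        {report.net_mV:+8.1f}"
        f"   ({'feasible' if report.feasible else 'NOT feasible'})",
        f"  heme b_P estimate (quinol symmetry)        {report.bp_estimate_mV:+8.1f}",
        f"  heme b_N estimate (b_P {scheme.bp_offset_to_bn:+.0f} mV trend)     "
        f"{report.bn_estimate_mV:+8.1f}",
    ]
    return "\n".join(lines)


def save_report(scheme: BifurcationScheme, report: EnergeticsReport, path: str | Path) -> Path:
    path = Path(path)
    payload = report.to_dict()
    payload["scheme"] = {
        "quinone": scheme.quinone.name,
        "rieske": scheme.rieske.name,
        "high_branch_acceptor": scheme.high_branch_acceptor.name,
        "low_branch_acceptor": scheme.low_branch_acceptor.name,
        "bp_offset_to_bn_mV": scheme.bp_offset_to_bn,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
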
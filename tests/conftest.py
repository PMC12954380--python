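import numpy as np
import pytest

from redoxpath import (
    AtomRecord,
    CofactorInstance,
    ProcessingConfig,
    SpectrumRecord,
    TitrationSeries,
)


@pytest.fixture
def config():
    return ProcessingConfig()


@pytest.fixture
def flat_series():
    """Three flat spectra (A=0.30) covering baseline window and analysis band."""
    wl = np.arange(400.0, 720.0, 2.0)
    spectra = [
        SpectrumRecord(wavelengths=wl, absorbances=np.full_like(wl, 0.30),
                       applied_potential=p, acquisition_index=i)
        for i, p in enumerate([-330.0, 0.0, 270.0])
    ]
    return TitrationSeries(spectra=spectra)


def single_atom_cofactor(label, xyz, kind="fe2s2", element="S"):
    """A one-atom cofactor: edge-to-edge distances equal point distances."""
    return CofactorInstance(
        kind=kind, label=label,
        atoms=[AtomRecord(serial=1, name=element.upper() + "1", element=element,
                          residue_name="FES", chain="X", residue_seq=1, xyz=tuple(xyz))],
    )


def zigzag_chain_with_shortcut():
    """Five one-atom cofactors: chain A-B-C-D-E spaced exactly 14 Å with a
    19 Å direct A-D shortcut; all other pairs are beyond 20 Å."""
    y = np.sqrt(14.0**2 - 2.5**2)
    coords = {
        "A": (0.0, 0.0, 0.0),
        "B": (2.5, y, 0.0),
        "C": (16.5, y, 0.0),
        "D": (19.0, 0.0, 0.0),
        "E": (19.0, -14.0, 0.0),
    }
    return [single_atom_cofactor(lbl, xyz) for lbl, xyz in coords.items()]
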
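"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from idpfrag.csp import PeakList


def make_peak_list(spectrum_id: str, positions: dict[str, tuple[float, float]],
                   field_mhz: float = 800.0) -> PeakList:
    """Peak list from {residue: (dH_ppm, dN_ppm)} with nominal linewidths."""
    rows = [
        {"residue": res, "dH_ppm": dh, "dN_ppm": dn, "intensity": 1.0,
         "lw_H_hz": 24.0, "lw_N_hz": 17.0, "snr": 10.0}
        for res, (dh, dn) in positions.items()
    ]
    return PeakList(spectrum_id, field_mhz, pd.DataFrame(rows))


def write_multimodel_pdb(path, frames: list[dict[int, np.ndarray]]) -> None:
    """Write CB-only TRP/TYR residues as a MODEL/ENDMDL multi-model PDB.

    ``frames`` maps residue number -> xyz per frame.
    """
    resname = {60: "TRP", 76: "TRP", 88: "TYR"}
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for res in sorted(coords):
                x, y, z = coords[res]
                fh.write(
                    f"ATOM  {serial:5d}  CB  {resname.get(res, 'ALA')} A"
                    f"{res:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"           C\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


@pytest.fixture
def rng():
    return np.random.default_rng(20150)
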
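import numpy as np
import pytest

from dnarad.nuclide_xsec import CrossSectionLibrary, NuclideCrossSectionTable
from dnarad.structure import LatticeSpec, build_slab, make_synthetic_cell


def constant_library(sigma_barn: dict) -> CrossSectionLibrary:
    """Library whose non-elastic cross section is constant in energy."""
    tables = {
        el: NuclideCrossSectionTable(
            element=el,
            energies=np.array([10.0, 1e11]),
            total=np.array([s + 1.0, s + 1.0]),
            elastic=np.array([1.0, 1.0]),
        )
        for el, s in sigma_barn.items()
    }
    return CrossSectionLibrary(tables)


@pytest.fixture
def disk_lattice():
    """5x5 carbon lattice (0.2 nm pitch) with non-overlapping 0.05 nm disks.

    Returns (slab, library, sigma_truth_barn): all 25 disks lie inside
    the 1 nm^2 sampling square, so the expected hit fraction is exactly
    25 * sigma / A.
    """
    from dnarad.mc import BARN_PER_NM2

    sigma_nm2 = np.pi * 0.05**2
    sigma_barn = sigma_nm2 * BARN_PER_NM2
    lib = constant_library({"C": sigma_barn})
    cell = make_synthetic_cell(
        LatticeSpec(element="C", shape=(5, 5, 1), pitch=0.2)
    )
    slab = build_slab(cell, 0.2, rng_seed=1, randomize=False)
    return slab, lib, sigma_barn


def write_pdb(path, records):
    """Write minimal fixed-column PDB records.

    records: list of (record, serial, name, resname, chain, resseq,
    x, y, z, element) with coordinates in angstrom.
    """
    lines = []
    for rec, serial, name, res, ch, seq, x, y, z, el in records:
        lines.append(
            f"{rec:<6s}{serial:5d} {name:<4s} {res:>3s} {ch}{seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
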
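"""Deterministic synthetic fixtures: structures, tables, curves, reads.

Every generator embeds its ground-truth parameters in a sidecar JSON so
recovery tests can compare estimates against the values that generated
the data.  All randomness flows through a seed argument.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure import LatticeSpec, UnitCell, make_synthetic_cell

__all__ = [
    "write_lattice_pdb",
    "generate_xsec_table",
    "generate_qpcr_curves",
    "random_sequences",
    "generate_reads",
    "write_fasta",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


def write_lattice_pdb(path: str, spec: LatticeSpec) -> UnitCell:
    """Write a synthetic lattice cell as a PDB file; returns the cell.

    Nucleotide sites are emitted as single-atom residues (DG/DC for GC
    sites, DA otherwise) and waters as HOH, so the file round-trips
    through :func:`dnarad.structure.read_structure`.
    """
    import gemmi

    cell = make_synthetic_cell(spec)
    st = gemmi.Structure()
    st.name = "synthetic lattice"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, atom in enumerate(cell.atoms, start=1):
        if atom.category == "water":
            resname = "HOH"
        elif atom.is_gc:
            resname = "DG"
        else:
            resname = "DA"
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "H" if resname == "HOH" else "A"
        a = gemmi.Atom()
        a.name = atom.element
        a.element = gemmi.Element(atom.element)
        x, y, z = (np.asarray(atom.position) * 10.0).tolist()  # nm -> A
        a.pos = gemmi.Position(x, y, z)
        a.occ = 1.0
        res.add_atom(a)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return cell


def generate_xsec_table(
    path: Optional[str] = None,
    elements: Sequence[str] = ("H", "C", "N", "O", "P"),
    n_points: int = 24,
    rng_seed: Optional[int] = None,
) -> pd.DataFrame:
    """Smooth synthetic total/elastic cross-section tables per element.

    Emulates the shape of tabulated neutron data: a gently rising
    non-elastic component above ~1 MeV plus an elastic floor, on a
    log-spaced grid over [1e4, 1e10] eV.  Writes CSV (+ sidecar JSON of
    generating parameters) when ``path`` is given.
    """
    rng = np.random.default_rng(rng_seed)
    energies = np.logspace(4, 10, n_points)
    frames = []
    truth = {}
    for el in elements:
        amp = float(rng.uniform(0.3, 1.5))
        slope = float(rng.uniform(0.05, 0.25))
        elastic0 = float(rng.uniform(1.0, 5.0))
        x = np.log10(energies)
        nonel = amp * np.clip(x - 6.0, 0.0, None) * (
            1.0 + slope * np.clip(x - 6.0, 0.0, None)
        )
        elastic = elastic0 * (1.0 + 0.1 * np.cos(x))
        frames.append(
            pd.DataFrame(
                dict(
                    element=el,
                    energy_eV=energies,
                    total_barn=nonel + elastic,
                    elastic_barn=elastic,
                )
            )
        )
        truth[el] = dict(amp=amp, slope=slope, elastic0=elastic0)
    df = pd.concat(frames, ignore_index=True)
    if path:
        df.to_csv(path, index=False)
        with open(str(path) + ".truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return df


def generate_qpcr_curves(
    path: Optional[str] = None,
    fluences: Sequence[float] = (0.0, 1.6e11, 2.4e11, 3.3e11, 4.2e11, 5.1e11),
    n_cycles: int = 40,
    noise_sd: float = 0.01,
    slope_per_fluence: float = 0.0,
    rng_seed: Optional[int] = None,
) -> pd.DataFrame:
    """Synthetic qPCR amplification curves, one sample per fluence.

    Curves follow a 4PL sigmoid with midpoint cycle shifted by
    ``slope_per_fluence * fluence`` (zero by default: the no-effect
    null) plus Gaussian noise of ``noise_sd`` (fraction of plateau).
    Ground-truth parameters go to a sidecar JSON when writing.
    """
    rng = np.random.default_rng(rng_seed)
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    records = []
    truth = {}
    for i, fl in enumerate(fluences):
        a, d = 0.05, 1.0
        b = float(rng.uniform(8.0, 12.0))
        c = 20.0 + slope_per_fluence * fl + float(rng.normal(0.0, 0.3))
        y = d + (a - d) / (1.0 + (cycles / c) ** b)
        y = y + rng.normal(0.0, noise_sd * d, size=y.shape)
        sid = f"S{i}"
        truth[sid] = dict(a=a, b=b, c=c, d=d, fluence=fl)
        for cyc, val in zip(cycles, y):
            records.append(
                dict(sample=sid, fluence=fl, cycle=cyc, fluorescence=val)
            )
    df = pd.DataFrame.from_records(records)
    if path:
        df.to_csv(path, index=False)
        with open(str(path) + ".truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return df


def random_sequences(n: int, length: int, rng_seed=None):
    """``n`` random DNA sequences of the given length."""
    rng = np.random.default_rng(rng_seed)
    return [
        "".join(rng.choice(_BASES, size=length)) for _ in range(n)
    ]


def generate_reads(
    references: Sequence[str],
    n_reads_per_ref: int = 10,
    insertion_rate: float = 0.0,
    deletion_rate: float = 0.0,
    substitution_rate: float = 0.0,
    rng_seed=None,
):
    """Simulate reads with independent per-base error rates.

    For each reference base: delete with p_del; otherwise emit the base,
    substituted with p_sub; after each emitted base insert a uniform
    random base with p_ins.  Returns ``(reads, refs_of_reads)`` lists.
    """
    for r in (insertion_rate, deletion_rate, substitution_rate):
        if not 0.0 <= r < 1.0:
            raise ValueError("error rates must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    reads, origins = [], []
    for ri, ref in enumerate(references):
        for _ in range(n_reads_per_ref):
            out = []
            for base in ref:
                if rng.random() < deletion_rate:
                    continue
                if rng.random() < substitution_rate:
                    others = [b for b in "ACGT" if b != base]
                    base = others[rng.integers(0, 3)]
                out.append(base)
                if rng.random() < insertion_rate:
                    out.append(_BASES[rng.integers(0, 4)])
            reads.append("".join(out))
            origins.append(ri)
    return reads, origins


def write_fasta(path: str, sequences: Sequence[str], prefix: str = "ref"):
    """Write sequences as FASTA with ids ``prefix0``, ``prefix1``, ..."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{prefix}{i}\n{seq}\n")


def write_fastq(path: str, sequences: Sequence[str], prefix: str = "read"):
    """Write sequences as FASTQ with uniform quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
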
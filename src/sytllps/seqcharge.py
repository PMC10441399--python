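"""Polyampholyte charge metrics for protein sequences.

Intrinsically disordered regions that phase separate are frequently strong
polyampholytes: they carry a high fraction of both positive and negative
residues arranged in charge blocks.  Three scalar descriptors capture this:

* **FCR** (fraction of charged residues) ``(n+ + n-)/N`` — a value above
  ~0.3 marks a "strong" polyampholyte.
* **NCPR** (net charge per residue) ``(n+ - n-)/N``.
* **SCD** (sequence charge decoration)
  ``(1/N) * sum_{m>n} q_m q_n sqrt(m-n)`` — a charge-patterning metric that
  is strongly negative for sequences whose opposite charges are arranged in
  blocks, a pattern conducive to liquid-liquid phase separation.

The module ships the wild-type synaptotagmin-1 juxtamembrane linker
(rat, UniProt P21707, residues 80-142) and a synthetic reconstruction of the
lysine-neutralised "JuxtaK" mutant as packaged FASTA fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Charge tables.  ``default`` treats histidine as neutral (appropriate at
#: pH 7.4, well above the His side-chain pKa); ``his-half`` assigns His +0.5
#: for users who want a population-averaged protonation near neutral pH.
CHARGE_SCHEMES: dict[str, dict[str, float]] = {
    "default": {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0},
    "his-half": {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.5},
}


class SequenceError(ValueError):
    """Invalid sequence input (empty, unknown residue letter, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (one-letter codes, N >= 1)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in AMINO_ACIDS:
                raise SequenceError(
                    f"sequence {self.id!r}: unknown residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ChargeProfile:
    """Per-residue charges q_i for one sequence under a named scheme."""

    charges: np.ndarray
    scheme_id: str
    sequence_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "charges", np.asarray(self.charges, dtype=float)
        )
        if self.charges.ndim != 1 or self.charges.size < 1:
            raise SequenceError("charge profile must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.charges.size


@dataclass(frozen=True)
class ChargeMetrics:
    """Scalar polyampholyte descriptors of one sequence."""

    f_plus: float
    f_minus: float
    fcr: float
    ncpr: float
    scd: float = field(default=np.nan)


def assign_charges(seq: SequenceRecord, scheme: str = "default") -> ChargeProfile:
    """Map each residue of *seq* to its formal charge under *scheme*.

    Residues absent from the scheme table (all polar/apolar residues, and
    His under the default scheme) carry charge 0.
    """
    try:
        table = CHARGE_SCHEMES[scheme]
    except KeyError:
        raise SequenceError(
            f"unknown charge scheme {scheme!r}; registered: {sorted(CHARGE_SCHEMES)}"
        ) from None
    charges = np.array([table.get(aa, 0.0) for aa in seq.residues])
    return ChargeProfile(charges=charges, scheme_id=scheme, sequence_id=seq.id)


def compute_fcr_ncpr(profile: ChargeProfile) -> ChargeMetrics:
    """FCR, NCPR and the positive/negative fractions of a charge profile."""
    q = profile.charges
    n = q.size
    f_plus = float(np.sum(q[q > 0])) / n
    f_minus = float(-np.sum(q[q < 0])) / n
    return ChargeMetrics(
        f_plus=f_plus,
        f_minus=f_minus,
        fcr=f_plus + f_minus,
        ncpr=f_plus - f_minus,
    )


def compute_scd(profile: ChargeProfile) -> float:
    """Sequence charge decoration: ``(1/N) sum_{m>n} q_m q_n sqrt(m-n)``.

    Negative values indicate sequences in which opposite charges are close
    and like charges are spread out (or blocky +/- arrangements); strongly
    negative SCD is predictive of salt-resilient polyampholyte phase
    separation.  Invariant under sequence reversal.
    """
    q = profile.charges
    n = q.size
    if n < 2:
        raise SequenceError("SCD requires at least two residues")
    idx = np.arange(n)
    # pairwise sqrt-separation matrix; strict upper triangle only
    sep = np.sqrt(np.abs(idx[:, None] - idx[None, :]))
    outer = np.outer(q, q)
    total = float(np.sum(np.triu(outer * sep, k=1)))
    return total / n


def metrics_report(
    records: Sequence[SequenceRecord], scheme: str = "default"
) -> pd.DataFrame:
    """One row of charge metrics per input record."""
    if len(records) == 0:
        raise SequenceError("metrics_report needs at least one sequence record")
    rows = []
    for rec in records:
        profile = assign_charges(rec, scheme)
        m = compute_fcr_ncpr(profile)
        rows.append(
            {
                "id": rec.id,
                "N": len(rec),
                "f_plus": m.f_plus,
                "f_minus": m.f_minus,
                "fcr": m.fcr,
                "ncpr": m.ncpr,
                "scd": compute_scd(profile) if len(rec) >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA input and packaged fixtures
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file."""
    records = [
        SequenceRecord(id=r.id, residues=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def _packaged_record(name: str) -> SequenceRecord:
    with resources.as_file(resources.files("sytllps.data") / name) as p:
        return read_fasta(p)[0]


def wt_linker() -> SequenceRecord:
    """Wild-type syt1 juxtamembrane linker, residues 80-142 (UniProt P21707)."""
    return _packaged_record("syt1_linker_wt.fasta")


def juxtak_linker() -> SequenceRecord:
    """Synthetic JuxtaK mutant linker: all lysines but K141 replaced by Gln.

    A reconstruction of the lysine-neutralised linker used to abolish
    self-association; the exact published substitution pattern is not
    redistributable, so this stand-in keeps one lysine (K141) and uses
    glutamine as the substituting polar residue throughout.
    """
    return _packaged_record("syt1_linker_juxtak_synthetic.fasta")
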
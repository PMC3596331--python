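"""Sequence I/O and physicochemical annotation.

Reads and writes protein FASTA, and computes the two per-protein
physicochemical quantities reported for every family member: average
molecular weight and isoelectric point (pI).

The pI is the root of the protein net-charge function, a
Henderson-Hasselbalch sum over the two termini and the ionisable side
chains (D, E, C, Y, H, K, R) with the Bjellqvist pK set packaged under
``xb3scan/data``.  Net charge is strictly decreasing in pH, so the root
on [0, 14] is unique and found by bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

WATER_MASS_DA = 18.0153


class SequenceError(ValueError):
    """Raised for malformed or non-canonical sequence input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its identifier and optional species tag."""

    id: str
    seq: str
    species: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PhyschemResult:
    """Average molecular weight (Da) and isoelectric point (pH units)."""

    mw: float
    pi: float


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("xb3scan.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


RESIDUE_MASSES_DA: dict[str, float] = {
    res: float(mass) for res, mass in _load_table("residue_masses.tsv")
}

#: (pK, sign) per ionisable group; sign +1 for basic, -1 for acidic groups.
PK_TABLE: dict[str, tuple[float, int]] = {
    grp: (float(pk), int(sign)) for grp, pk, sign in _load_table("pk_bjellqvist.tsv")
}


def normalize_sequence(raw: str) -> str:
    """Uppercase and strip a single trailing stop character.

    Internal stop characters indicate a truncated gene model and raise
    :class:`SequenceError` rather than passing silently.
    """
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise SequenceError("internal stop character '*' in sequence")
    return seq


def _check_canonical(seq: str) -> str | None:
    """Return the first non-canonical residue letter, or None."""
    for ch in seq:
        if ch not in CANONICAL_RESIDUES:
            return ch
    return None


def read_fasta(
    path: str | Path,
    on_invalid: Literal["warn", "error"] = "warn",
) -> list[ProteinRecord]:
    """Parse a protein FASTA file into validated :class:`ProteinRecord` objects.

    Wrapped and unwrapped sequence lines are both accepted; file order is
    preserved.  Sequences are uppercased and a trailing ``*`` is stripped.
    Records containing non-canonical residues (B, J, O, U, X, Z, ...) are
    excluded with a warning under the default policy, or abort the parse
    when ``on_invalid="error"``.  Duplicate identifiers always abort.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    duplicates: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            duplicates.append(name)
            continue
        try:
            seq = normalize_sequence(str(rec.seq))
        except SequenceError as exc:
            if on_invalid == "error":
                raise SequenceError(f"record {name!r}: {exc}") from exc
            warnings.warn(f"record {name!r} rejected: {exc}", stacklevel=2)
            continue
        bad = _check_canonical(seq)
        if bad is not None or not seq:
            msg = (
                f"record {name!r} rejected: "
                + (f"non-canonical residue {bad!r}" if bad else "empty sequence")
            )
            if on_invalid == "error":
                raise SequenceError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        records.append(ProteinRecord(id=name, seq=seq, species=_species_tag(rec.description)))
    if duplicates:
        raise SequenceError(
            f"duplicate identifiers in {path.name}: {sorted(set(duplicates))}"
        )
    return records


def _species_tag(description: str) -> str:
    """Extract a ``species=...`` tag from a FASTA description, if present."""
    for token in description.split():
        if token.startswith("species="):
            return token.removeprefix("species=")
    return ""


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips losslessly with read_fasta."""
    seq_records = []
    for rec in records:
        description = f"species={rec.species}" if rec.species else ""
        seq_records.append(SeqRecord(Seq(rec.seq), id=rec.id, description=description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def molecular_weight(seq: str) -> float:
    """Average molecular mass in Daltons: residue masses plus one water."""
    if not seq:
        raise SequenceError("cannot compute molecular weight of empty sequence")
    try:
        total = sum(RESIDUE_MASSES_DA[res] for res in seq)
    except KeyError as exc:
        raise SequenceError(f"non-canonical residue {exc.args[0]!r}") from exc
    return total + WATER_MASS_DA


def net_charge(seq: str, ph: float) -> float:
    """Protein net charge at a given pH (Henderson-Hasselbalch sum).

    Basic groups contribute +1/(1+10^(pH-pK)); acidic groups contribute
    -1/(1+10^(pK-pH)).  Strictly decreasing in pH for every sequence.
    """
    if not seq:
        raise SequenceError("cannot compute charge of empty sequence")

    def positive(pk: float, count: int) -> float:
        return count / (1.0 + 10.0 ** (ph - pk))

    def negative(pk: float, count: int) -> float:
        return -count / (1.0 + 10.0 ** (pk - ph))

    charge = positive(PK_TABLE["Nterm"][0], 1) + negative(PK_TABLE["Cterm"][0], 1)
    for res in "DECYHKR":
        count = seq.count(res)
        if not count:
            continue
        pk, sign = PK_TABLE[res]
        charge += positive(pk, count) if sign > 0 else negative(pk, count)
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The returned pI satisfies ``abs(net_charge(seq, pi)) < 1e-3`` for any
    sequence whose charge actually crosses zero inside the bracket (always
    true with the packaged pK set, whose extreme values are 3.55 and 12).
    """
    if not seq:
        raise SequenceError("cannot compute pI of empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physchem(seq: str) -> PhyschemResult:
    """Molecular weight and pI in one call."""
    return PhyschemResult(mw=molecular_weight(seq), pi=isoelectric_point(seq))
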
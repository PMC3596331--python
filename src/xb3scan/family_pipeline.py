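"""Family membership pipeline: XB3-like = >=2 ANK repeats + one C3HC4 RING.

Runs the ANK and RING scanners, the group classifier and the physchem
annotations over a whole proteome, isolates per-record failures, and
writes/reads the deterministic TSV report that downstream steps diff.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .ank_domain import DEFAULT_ANK_THRESHOLD, AnkAnnotation, scan_ank
from .ring_domain import RingDomain, classify_group, scan_ring
from .seqio import ProteinRecord, isoelectric_point, molecular_weight

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "id",
    "species",
    "is_member",
    "reason",
    "ank_count",
    "ank_class",
    "ank_intervals",
    "ring_ligands",
    "d67",
    "group",
    "after_L7",
    "after_L8",
    "before_L2",
    "mw",
    "pi",
)


@dataclass(frozen=True)
class PipelineConfig:
    strictness: str = "strict"
    ank_threshold: float = DEFAULT_ANK_THRESHOLD

    def digest(self) -> str:
        payload = f"strictness={self.strictness};ank_threshold={self.ank_threshold}"
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FamilyAnnotation:
    """Per-protein verdict with all supporting annotations.

    ``ring`` is the classifying (leftmost accepted) RING domain; every
    accepted domain is retained in ``rings``.
    """

    id: str
    species: str
    is_member: bool
    reason: str
    ank: AnkAnnotation
    rings: list[RingDomain] = field(default_factory=list)
    group: str = ""
    mw: float = 0.0
    pi: float = 0.0
    length: int = 0

    @property
    def ring(self) -> RingDomain | None:
        return self.rings[0] if self.rings else None


def annotate_protein(record: ProteinRecord, config: PipelineConfig) -> FamilyAnnotation:
    ank = scan_ank(record, threshold=config.ank_threshold)
    rings = scan_ring(record, strictness=config.strictness)
    reasons = []
    if ank.count < 2:
        reasons.append(f"ANK count {ank.count} < 2")
    if not rings:
        reasons.append("no accepted C3HC4 RING domain")
    is_member = not reasons
    group = ""
    if is_member:
        group = classify_group(rings[0]).group
        reasons.append(f"member: {ank.count} ANK + RING at {rings[0].start}, group {group}")
    return FamilyAnnotation(
        id=record.id,
        species=record.species,
        is_member=is_member,
        reason="; ".join(reasons),
        ank=ank,
        rings=rings,
        group=group,
        mw=molecular_weight(record.seq),
        pi=isoelectric_point(record.seq),
        length=len(record.seq),
    )


def annotate_proteome(
    records: Sequence[ProteinRecord], config: PipelineConfig | None = None
) -> list[FamilyAnnotation]:
    """Annotate every record; one bad record never aborts the run."""
    if not records:
        raise ValueError("empty input: no protein records to annotate")
    config = config or PipelineConfig()
    out = []
    for record in records:
        try:
            out.append(annotate_protein(record, config))
        except Exception:
            logger.exception("annotation failed for record %r; skipping", record.id)
    return out


@dataclass(frozen=True)
class CohortSummary:
    n_proteins: int
    n_members: int
    by_species: dict[str, int]
    by_group: dict[str, int]
    by_class: dict[str, int]
    length_range: tuple[int, int] | None
    pi_range: tuple[float, float] | None


def summarize_cohort(annotations: Sequence[FamilyAnnotation]) -> CohortSummary:
    """Member counts by species, group I-III and class A-F, plus ranges.

    Group and class counts partition the member set; length and pI ranges
    are over members only (None when there are no members).
    """
    if not annotations:
        raise ValueError("no annotations to summarise")
    members = [a for a in annotations if a.is_member]
    by_species: dict[str, int] = {}
    by_group = {g: 0 for g in ("I", "II", "III", "unassigned")}
    by_class = {c: 0 for c in ("A", "B", "C", "D", "E", "F", "unclassified")}
    for a in members:
        by_species[a.species] = by_species.get(a.species, 0) + 1
        by_group[a.group] = by_group.get(a.group, 0) + 1
        by_class[a.ank.ank_class] = by_class.get(a.ank.ank_class, 0) + 1
    member_lengths = [a.length for a in members]
    return CohortSummary(
        n_proteins=len(annotations),
        n_members=len(members),
        by_species=by_species,
        by_group=by_group,
        by_class=by_class,
        length_range=(min(member_lengths), max(member_lengths)) if members else None,
        pi_range=(
            round(min(a.pi for a in members), 2),
            round(max(a.pi for a in members), 2),
        )
        if members
        else None,
    )


def _annotation_row(a: FamilyAnnotation) -> dict:
    ring = a.ring
    flags = ring.signature_flags if ring else {}
    return {
        "id": a.id,
        "species": a.species,
        "is_member": str(a.is_member).lower(),
        "reason": a.reason,
        "ank_count": a.ank.count,
        "ank_class": a.ank.ank_class,
        "ank_intervals": ",".join(f"{r.start}-{r.end}" for r in a.ank.repeats),
        "ring_ligands": ",".join(str(p) for p in ring.ligand_pos) if ring else "",
        "d67": ring.d67 if ring else "",
        "group": a.group,
        "after_L7": str(flags.get("after_L7", "")).lower(),
        "after_L8": str(flags.get("after_L8", "")).lower(),
        "before_L2": str(flags.get("before_L2", "")).lower(),
        "mw": f"{a.mw:.2f}",
        "pi": f"{a.pi:.2f}",
    }


def write_report(
    annotations: Iterable[FamilyAnnotation],
    path: str | Path,
    config: PipelineConfig | None = None,
) -> None:
    """Deterministic TSV report with a provenance comment line."""
    config = config or PipelineConfig()
    df = pd.DataFrame([_annotation_row(a) for a in annotations], columns=REPORT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# xb3scan {__version__} config={config.digest()}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
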
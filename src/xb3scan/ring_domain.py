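"""C3HC4 RING-finger detection and group I/II/III classification.

The C3HC4 RING finger binds two zinc ions in a cross-brace arrangement:
eight metal ligands (seven Cys plus one His at position 4, pattern
C,C,C,H,C,C,C,C) in which ligand pairs 1&3 chelate one zinc and pairs 2&4
the other.  The cross-brace geometry fixes the spacings between ligands
1-2, 3-6 and 7-8 while the 2-3 and 6-7 stretches may vary across RING
subtypes.  In the XB3-like family the conserved spacings are family
specific constants:

    d12 = 2, d23 = 11, d36 = 7 (counting the intervening ligands 4 and 5),
    d78 = 2, and d67 anywhere in [11, 24].

A spacing ``dij`` counts residues lying *strictly between* ligand i and
ligand j.  The d67 spacing, together with a handful of conserved
non-ligand residues, separates the family's three phylogenetic groups:

    group I   d67 in 19..23, Leu immediately before ligand 8
    group II  d67 in 21..24, Phe before ligand 8, Gly before ligand 4
    group III d67 == 11,     Val or Ile before ligand 8

with Pro right after ligand 7, Arg right after ligand 8 and Val/Ile right
before ligand 2 shared by all groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import pandas as pd

from .seqio import ProteinRecord

#: inclusive window for the variable ligand 6 -> 7 spacing
D67_MIN, D67_MAX = 11, 24

#: sub-spacing windows inside the fixed L3..L6 stretch (canonical C3HC4)
L3_L4_SPACINGS = (1, 2, 3)
L4_L5_SPACINGS = (2, 3)

SIGNATURE_RESIDUES = {
    "after_L7": frozenset("P"),
    "after_L8": frozenset("R"),
    "before_L2": frozenset("VI"),
}


@dataclass(frozen=True)
class GroupSignature:
    """Group-discriminating d67 window and before-ligand-8/4 residue sets."""

    group: str
    d67_window: tuple[int, int]
    before_L8: frozenset[str]
    before_L4: frozenset[str] | None = None  # None = unconstrained


GROUP_SIGNATURES: tuple[GroupSignature, ...] = (
    GroupSignature("I", (19, 23), frozenset("L")),
    GroupSignature("II", (21, 24), frozenset("F"), frozenset("G")),
    GroupSignature("III", (11, 11), frozenset("VI")),
)


@dataclass
class RingDomain:
    """An accepted C3HC4 match: ligand coordinates (1-based), spacings, group.

    ``start``/``end`` are the positions of ligands 1 and 8.  ``context``
    holds the protein subsequence from ligand 1 through one residue past
    ligand 8 (when it exists), so signature residues can be re-read without
    the parent record.
    """

    protein_id: str
    ligand_pos: tuple[int, int, int, int, int, int, int, int]
    ligand_res: tuple[str, ...]
    context: str
    after_L8_res: str | None
    group: str = "unassigned"
    signature_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = self.ligand_pos
        if list(pos) != sorted(set(pos)):
            raise ValueError("ligand positions must be strictly increasing")
        if tuple(self.ligand_res) != tuple("CCCHCCCC"):
            raise ValueError("ligand residues must follow the C3HC4 pattern C,C,C,H,C,C,C,C")
        if not (self.d12 == 2 and self.d78 == 2 and self.d23 == 11 and self.d36 == 7):
            raise ValueError("fixed spacings violated: need d12=2, d23=11, d36=7, d78=2")
        if not D67_MIN <= self.d67 <= D67_MAX:
            raise ValueError(f"d67={self.d67} outside [{D67_MIN}, {D67_MAX}]")

    @property
    def start(self) -> int:
        return self.ligand_pos[0]

    @property
    def end(self) -> int:
        return self.ligand_pos[7]

    def _between(self, i: int, j: int) -> int:
        return self.ligand_pos[j] - self.ligand_pos[i] - 1

    @property
    def d12(self) -> int:
        return self._between(0, 1)

    @property
    def d23(self) -> int:
        return self._between(1, 2)

    @property
    def d36(self) -> int:
        # residues strictly between L3 and L6; ligands 4 and 5 are counted
        return self._between(2, 5)

    @property
    def d67(self) -> int:
        return self._between(5, 6)

    @property
    def d78(self) -> int:
        return self._between(6, 7)

    def _context_res(self, pos: int) -> str | None:
        offset = pos - self.start
        if offset < 0 or offset >= len(self.context):
            return None
        return self.context[offset]

    @property
    def before_L2_res(self) -> str | None:
        return self._context_res(self.ligand_pos[1] - 1)

    @property
    def before_L4_res(self) -> str | None:
        return self._context_res(self.ligand_pos[3] - 1)

    @property
    def after_L7_res(self) -> str | None:
        return self._context_res(self.ligand_pos[6] + 1)

    @property
    def before_L8_res(self) -> str | None:
        return self._context_res(self.ligand_pos[7] - 1)


@dataclass(frozen=True)
class GroupCall:
    """Outcome of group classification with the rule trace that produced it."""

    group: str
    trace: tuple[str, ...]
    signature_flags: dict[str, bool]


def _signature_flags(domain: RingDomain) -> dict[str, bool]:
    flags = {
        "after_L7": domain.after_L7_res in SIGNATURE_RESIDUES["after_L7"],
        "after_L8": (domain.after_L8_res or "") in SIGNATURE_RESIDUES["after_L8"],
        "before_L2": domain.before_L2_res in SIGNATURE_RESIDUES["before_L2"],
        "before_L4_G": domain.before_L4_res == "G",
    }
    return flags


def _candidate_tuples(seq: str) -> list[tuple[int, ...]]:
    """All 0-based 8-tuples satisfying the ligand pattern and spacings."""
    n = len(seq)
    out: list[tuple[int, ...]] = []
    for l1 in range(n):
        if seq[l1] != "C":
            continue
        l2 = l1 + 3  # d12 = 2
        l3 = l2 + 12  # d23 = 11
        if l3 >= n or seq[l2] != "C" or seq[l3] != "C":
            continue
        l6 = l3 + 8  # d36 = 7
        if l6 >= n or seq[l6] != "C":
            continue
        for s34 in L3_L4_SPACINGS:
            l4 = l3 + s34 + 1
            if seq[l4] != "H":
                continue
            for s45 in L4_L5_SPACINGS:
                l5 = l4 + s45 + 1
                if l5 >= l6 or seq[l5] != "C":
                    continue
                for d67 in range(D67_MIN, D67_MAX + 1):
                    l7 = l6 + d67 + 1
                    l8 = l7 + 3  # d78 = 2
                    if l8 >= n or seq[l7] != "C" or seq[l8] != "C":
                        continue
                    out.append((l1, l2, l3, l4, l5, l6, l7, l8))
    return out


def _resolve_overlaps(tuples: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Greedy left-to-right selection: sort by (start, end), keep non-overlapping."""
    chosen: list[tuple[int, ...]] = []
    for tup in sorted(tuples, key=lambda t: (t[0], t[7])):
        if chosen and tup[0] <= chosen[-1][7]:
            continue
        chosen.append(tup)
    return chosen


def _build_domain(record: ProteinRecord, tup: tuple[int, ...]) -> RingDomain:
    seq = record.seq
    l1, l8 = tup[0], tup[7]
    after = seq[l8 + 1] if l8 + 1 < len(seq) else None
    context_end = l8 + 2 if after is not None else l8 + 1
    domain = RingDomain(
        protein_id=record.id,
        ligand_pos=tuple(p + 1 for p in tup),  # 1-based
        ligand_res=tuple(seq[p] for p in tup),
        context=seq[l1:context_end],
        after_L8_res=after,
    )
    domain.signature_flags = _signature_flags(domain)
    return domain


def scan_ring(
    record: ProteinRecord,
    strictness: Literal["strict", "signature-tolerant"] = "strict",
) -> list[RingDomain]:
    """Locate C3HC4 RING domains under the family spacing constraints.

    Matches the pattern C-x2-C-x11-C-x(1-3)-H-x(2-3)-C-x(s)-C-x(11-24)-C-x2-C
    with exactly 7 residues strictly between ligands 3 and 6.  Overlapping
    candidates are resolved greedily left to right (ties by smaller end).
    In ``strict`` mode the shared signature residues (Pro after ligand 7,
    Arg after ligand 8, Val/Ile before ligand 2) are required; in
    ``signature-tolerant`` mode they are recorded as flags only, so known
    family exceptions are still detected but flagged.
    """
    domains = [_build_domain(record, tup) for tup in _resolve_overlaps(_candidate_tuples(record.seq))]
    if strictness == "strict":
        domains = [
            d for d in domains
            if d.signature_flags["after_L7"]
            and d.signature_flags["after_L8"]
            and d.signature_flags["before_L2"]
        ]
    elif strictness != "signature-tolerant":
        raise ValueError(f"unknown strictness {strictness!r}")
    return domains


def classify_group(domain: RingDomain) -> GroupCall:
    """Assign group I/II/III from d67 and the before-ligand-8 residue.

    d67 == 11 is diagnostic for group III and 24 for group II; 19-20 can
    only be group I.  In the 21-23 overlap of the group I and II windows
    the before-ligand-8 residue (Leu vs Phe) decides; anything else is
    ``unassigned`` with the failed tests listed in the trace.  The result
    is also written back onto ``domain.group``.
    """
    flags = _signature_flags(domain)
    d67 = domain.d67
    b8 = domain.before_L8_res
    trace: list[str] = [f"d67={d67}", f"before_L8={b8}"]

    if not D67_MIN <= d67 <= D67_MAX:
        trace.append(f"d67 outside [{D67_MIN},{D67_MAX}]: unassigned")
        group = "unassigned"
    elif d67 == 11:
        trace.append("d67==11 -> group III")
        group = "III"
        if b8 not in {"V", "I"}:
            trace.append(f"warning: before_L8={b8} not in {{V,I}} expected for III")
    elif d67 in (19, 20):
        trace.append("d67 in {19,20}: only group I window -> group I")
        group = "I"
    elif d67 == 24:
        trace.append("d67==24: only group II window -> group II")
        group = "II"
    elif 21 <= d67 <= 23:
        trace.append("d67 in 21..23: group I/II windows overlap, resolve by before_L8")
        if b8 == "L":
            trace.append("before_L8==L -> group I")
            group = "I"
        elif b8 == "F":
            trace.append("before_L8==F -> group II")
            group = "II"
        else:
            trace.append(f"before_L8={b8} resolves neither I nor II -> unassigned")
            group = "unassigned"
    else:
        trace.append("d67 in no group window -> unassigned")
        group = "unassigned"

    domain.group = group
    domain.signature_flags = flags
    return GroupCall(group=group, trace=tuple(trace), signature_flags=flags)


# fixed column widths for the anchored consensus layout
_FIXED_L1_L6 = 24  # L1..L6 inclusive: 1+2+1+11+1+7+1 (d12,d23,d36 fixed)
_VAR_WIDTH = D67_MAX  # the d67 stretch, right-justified with '-' padding
_TAIL = 5  # L7, two residues, L8, after-L8


def _aligned_region(domain: RingDomain) -> str:
    pos = domain.ligand_pos
    ctx = domain.context
    start = domain.start
    l1_l6 = ctx[: pos[5] - start + 1]
    var = ctx[pos[5] - start + 1 : pos[6] - start]
    tail = ctx[pos[6] - start :].ljust(_TAIL, "-")
    return l1_l6 + var.rjust(_VAR_WIDTH, "-") + tail


def signature_report(domains: Iterable[RingDomain]) -> pd.DataFrame:
    """Per-group consensus of the RING region across a classified cohort.

    Columns are anchored on the eight ligand positions; the variable
    ligand 6 -> 7 stretch is right-justified and gap-padded.  For every
    group the member count and, per column, the majority residue with its
    frequency are reported.

    Returns a tidy frame with columns: group, n, column, majority, frequency.
    """
    domains = list(domains)
    if not domains:
        raise ValueError("signature_report requires at least one classified domain")
    rows = []
    by_group: dict[str, list[str]] = {}
    for dom in domains:
        by_group.setdefault(dom.group, []).append(_aligned_region(dom))
    for group in sorted(by_group):
        regions = by_group[group]
        width = _FIXED_L1_L6 + _VAR_WIDTH + _TAIL
        for col in range(width):
            counts: dict[str, int] = {}
            for region in regions:
                counts[region[col]] = counts.get(region[col], 0) + 1
            majority = max(sorted(counts), key=counts.get)
            rows.append(
                {
                    "group": group,
                    "n": len(regions),
                    "column": col + 1,
                    "majority": majority,
                    "frequency": counts[majority] / len(regions),
                }
            )
    return pd.DataFrame(rows)


#: worked exemplar of a group III RING region used in docs and tests:
#: ligands at 1,4,16,18,21,24,36,39 with d12=2, d23=11, d36=7, d67=11, d78=2.
GROUP_III_EXEMPLAR = "CAVC" + "A" * 11 + "CAHAACAAC" + "A" * 11 + "CPVCR"
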
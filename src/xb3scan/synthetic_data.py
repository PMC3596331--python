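"""Ground-truthed synthetic inputs for every stage of the pipeline.

Real family surveys start from whole proteomes and wet-lab RNA; neither is
reproducible at desk scale, so this module emulates them: proteins carrying
2-7 tandem 33-residue ANK repeats plus one C3HC4 RING built from a chosen
group's spacing/signature rules, negative decoys with named defects,
aligned families evolved down a known tree, and qPCR Ct tables with
programmed log2 effects and Gaussian replicate noise.

Every generator is a pure function of (spec, seed) and validates its own
truth record against the emitted sequence before returning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .ank_domain import ANK_CONSENSUS, ANK_REPEAT_LENGTH
from .expression import CtTable
from .phylogeny import Alignment
from .seqio import ProteinRecord

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: RING-internal filler alphabet: no Cys/His, so the embedded ligand set is
#: unambiguous inside the domain (flanks are unrestricted on purpose).
RING_FILLER = "".join(c for c in RESIDUES if c not in "CH")

GROUP_D67_WINDOWS = {"I": (19, 23), "II": (21, 24), "III": (11, 11)}
GROUP_BEFORE_L8 = {"I": "L", "II": "F", "III": "VI"}


@dataclass(frozen=True)
class SyntheticProteinSpec:
    """Recipe for one synthetic family member."""

    group: str = "III"
    n_ank: int = 3
    d67: int | None = None  # None: drawn from the group window
    flank_len: int = 30
    linker_len: int = 20
    mutations_per_ank: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUP_D67_WINDOWS:
            raise ValueError(f"unknown group {self.group!r}")
        lo, hi = GROUP_D67_WINDOWS[self.group]
        if self.d67 is not None and not lo <= self.d67 <= hi:
            raise ValueError(f"d67={self.d67} outside group {self.group} window [{lo},{hi}]")
        if not 1 <= self.n_ank:
            raise ValueError("n_ank must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Emitted record plus the generation-time ground truth."""

    record: ProteinRecord
    is_member: bool
    group: str | None = None
    ank_intervals: tuple[tuple[int, int], ...] = ()  # 1-based inclusive
    ligand_pos: tuple[int, ...] = ()  # 1-based, 8 entries for members
    kind: str = "member"


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = RESIDUES) -> str:
    return "".join(rng.choice(list(alphabet), size=length)) if length else ""


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    if k == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        alternatives = [c for c in RESIDUES if c != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _build_ring(rng: np.random.Generator, group: str, d67: int) -> tuple[str, tuple[int, ...]]:
    """RING region string and the 0-based ligand offsets within it.

    Layout: C x V/I C x11 C (before_L4) H x2 C x2 C x(d67) C P (before_L8) C R,
    i.e. sub-spacings L3-L4=1, L4-L5=2, L5-L6=2 so exactly 7 residues lie
    strictly between ligands 3 and 6.
    """
    f = lambda n: _random_seq(rng, n, RING_FILLER)
    before_l2 = "VI"[rng.integers(2)]
    before_l4 = "G" if group == "II" else f(1)
    before_l8 = GROUP_BEFORE_L8[group]
    if len(before_l8) > 1:
        before_l8 = before_l8[rng.integers(len(before_l8))]
    parts = [
        "C", f(1) + before_l2, "C", f(11), "C", before_l4, "H", f(2), "C", f(2),
        "C", f(d67), "C", "P" + before_l8, "C", "R",
    ]
    region = "".join(parts)
    offsets = []
    pos = 0
    for part in parts:
        if part in "CH" and len(part) == 1:
            offsets.append(pos)
        pos += len(part)
    return region, tuple(offsets)


def make_member(spec: SyntheticProteinSpec) -> SyntheticTruth:
    """Synthesise one family member with exact ANK/RING ground truth.

    Sequence layout: N-flank, ``n_ank`` tandem (optionally mutated) copies
    of the packaged ANK consensus, a linker, the group-specific RING
    region, C-flank.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = GROUP_D67_WINDOWS[spec.group]
    d67 = spec.d67 if spec.d67 is not None else int(rng.integers(lo, hi + 1))

    n_flank = _random_seq(rng, spec.flank_len)
    repeats = [
        _mutate(rng, ANK_CONSENSUS, spec.mutations_per_ank) for _ in range(spec.n_ank)
    ]
    linker = _random_seq(rng, spec.linker_len)
    ring, ring_offsets = _build_ring(rng, spec.group, d67)
    c_flank = _random_seq(rng, spec.flank_len)

    seq = n_flank + "".join(repeats) + linker + ring + c_flank
    ank_start = spec.flank_len
    ank_intervals = tuple(
        (ank_start + i * ANK_REPEAT_LENGTH + 1, ank_start + (i + 1) * ANK_REPEAT_LENGTH)
        for i in range(spec.n_ank)
    )
    ring_start = ank_start + spec.n_ank * ANK_REPEAT_LENGTH + spec.linker_len
    ligand_pos = tuple(ring_start + off + 1 for off in ring_offsets)

    truth = SyntheticTruth(
        record=ProteinRecord(id=f"syn_{spec.group}_{spec.n_ank}ank_s{spec.seed}", seq=seq),
        is_member=True,
        group=spec.group,
        ank_intervals=ank_intervals,
        ligand_pos=ligand_pos,
    )
    _self_check(truth)
    return truth


def _self_check(truth: SyntheticTruth) -> None:
    """Verify the truth record against the emitted sequence by direct indexing."""
    seq = truth.record.seq
    if truth.ligand_pos:
        residues = "".join(seq[p - 1] for p in truth.ligand_pos)
        assert residues == "CCCHCCCC", f"ligand self-check failed: {residues}"
        l7, l8 = truth.ligand_pos[6], truth.ligand_pos[7]
        assert seq[l7] == "P" and seq[l8] == "R"
    for start, end in truth.ank_intervals:
        assert end - start + 1 == ANK_REPEAT_LENGTH
        assert 1 <= start <= end <= len(seq)


def make_decoy(kind: str, seed: int = 0) -> SyntheticTruth:
    """A non-member with a named defect.

    Kinds: ``ring_only`` (valid RING, zero ANK), ``single_ank`` (one ANK +
    valid RING), ``c3h2c3`` (His in the ligand-5 slot, not a C3HC4 RING),
    ``shuffled`` (a member sequence randomly permuted).
    """
    rng = np.random.default_rng(seed)
    if kind == "ring_only":
        ring, _ = _build_ring(rng, "III", 11)
        seq = _random_seq(rng, 60) + ring + _random_seq(rng, 30)
    elif kind == "single_ank":
        ring, _ = _build_ring(rng, "III", 11)
        seq = _random_seq(rng, 30) + ANK_CONSENSUS + _random_seq(rng, 20) + ring + _random_seq(rng, 30)
    elif kind == "c3h2c3":
        ring, offsets = _build_ring(rng, "III", 11)
        ring = ring[: offsets[4]] + "H" + ring[offsets[4] + 1 :]  # ligand 5 C -> H
        seq = (
            _random_seq(rng, 30)
            + ANK_CONSENSUS * 2
            + _random_seq(rng, 20)
            + ring
            + _random_seq(rng, 30)
        )
    elif kind == "shuffled":
        member = make_member(SyntheticProteinSpec(seed=seed))
        seq = "".join(rng.permutation(list(member.record.seq)))
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    return SyntheticTruth(
        record=ProteinRecord(id=f"decoy_{kind}_s{seed}", seq=seq),
        is_member=False,
        kind=kind,
    )


def make_family(
    tree: dendropy.Tree | str,
    root_spec: SyntheticProteinSpec | None = None,
    rate: float = 0.1,
    seed: int = 0,
) -> tuple[Alignment, dendropy.Tree]:
    """Evolve a root member sequence down a known tree; return the (trivially
    aligned, indel-free) leaf matrix and the generating tree.

    ``rate`` is the expected number of substitutions per site per unit
    branch length; each site on an edge of length L substitutes with
    probability 1 - exp(-rate*L), uniformly over the 19 alternatives.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    root_truth = make_member(root_spec or SyntheticProteinSpec(seed=seed))
    root_seq = np.array(list(root_truth.record.seq))
    residues = np.array(list(RESIDUES))

    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_seq}
    labels: list[str] = []
    rows: list[str] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        length = node.edge.length or 0.0
        p_sub = 1.0 - np.exp(-rate * length)
        child = parent_seq.copy()
        hits = np.nonzero(rng.random(len(child)) < p_sub)[0]
        for pos in hits:
            alternatives = residues[residues != child[pos]]
            child[pos] = alternatives[rng.integers(len(alternatives))]
        seqs[node] = child
        if node.is_leaf():
            labels.append(node.taxon.label)
            rows.append("".join(child))
    return Alignment(labels=tuple(labels), rows=tuple(rows)), tree


def make_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    replicates: int = 3,
    log2_effects: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    baseline_dct: float = 5.0,
    reference_genes: Sequence[str] = ("RefA",),
) -> CtTable:
    """Simulate a qPCR Ct table with programmed per-gene log2 effects.

    Reference genes cycle at Ct 20 + noise in every condition; a target
    gene cycles at 20 + ``baseline_dct`` - effect + noise, so a positive
    log2 effect raises its expression by exactly that factor of two.
    Gaussian replicate noise has standard deviation ``noise_sd`` cycles.
    """
    if replicates < 2:
        raise ValueError("at least 2 replicates are required")
    rng = np.random.default_rng(seed)
    log2_effects = log2_effects or {}
    rows = []
    for gene in list(reference_genes) + [g for g in genes if g not in reference_genes]:
        is_ref = gene in reference_genes
        for cond in conditions:
            effect = 0.0 if is_ref else float(log2_effects.get(gene, {}).get(cond, 0.0))
            mu = 20.0 if is_ref else 20.0 + baseline_dct - effect
            for rep in range(1, replicates + 1):
                ct = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append({"gene": gene, "condition": cond, "replicate": rep, "ct": ct})
    return CtTable(data=pd.DataFrame(rows), reference_genes=tuple(reference_genes))
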
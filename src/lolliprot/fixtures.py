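"""Synthetic input generators.

Every other module is testable without downloads: this module fabricates
mutation sets (uniform or clustered), domain architectures, PTM lists
and alignments with controlled per-position identity, all reproducible
from a seed.  The flagship generator emulates the RET proto-oncogene
case: evenly distributed disease mutations plus a MEN2A-like cluster of
cysteine substitutions just N-terminal of the transmembrane domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .io_formats import (
    AA_LETTERS,
    AlignmentSet,
    DomainAnnotation,
    MutationRecord,
    ProteinContext,
    PTMSite,
)

_AA = np.array(list(AA_LETTERS))


@dataclass(frozen=True)
class ClusterSpec:
    """A mutation hotspot: window centre, half-width, and the fraction
    of all simulated mutations drawn from the window."""

    center: int
    half_width: int
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"cluster fraction must be in [0,1], got {self.fraction}")
        if self.half_width < 0:
            raise ValueError("cluster half_width must be >= 0")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the simulators; one seeded generator per call."""

    protein_length: int = 1114
    n_mutations: int = 24
    cluster: Optional[ClusterSpec] = None
    n_alignment_sequences: int = 7
    identity_profile: Optional[Sequence[float]] = None
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")
        if self.cluster is not None:
            lo = self.cluster.center - self.cluster.half_width
            hi = self.cluster.center + self.cluster.half_width
            if lo < 1 or hi > self.protein_length:
                raise ValueError(
                    f"cluster window [{lo}, {hi}] outside protein 1..{self.protein_length}"
                )
        if self.identity_profile is not None and len(self.identity_profile) != self.protein_length:
            raise ValueError("identity_profile length must equal protein_length")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")


def _random_substitution(rng: np.random.Generator) -> tuple[str, str]:
    ref = _AA[rng.integers(len(_AA))]
    alt = _AA[rng.integers(len(_AA) - 1)]
    if alt == ref:  # remap the collision to the excluded last letter
        alt = _AA[-1]
    return str(ref), str(alt)


def simulate_mutations(config: FixtureConfig) -> list[MutationRecord]:
    """Draw ``n_mutations`` records, optionally concentrating a fraction
    of them in a cluster window; ref != alt always."""
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_mutations
    if config.cluster is not None:
        n_clustered = round(config.cluster.fraction * n)
        lo = config.cluster.center - config.cluster.half_width
        hi = config.cluster.center + config.cluster.half_width
        if hi < lo:
            raise ValueError("cluster window is empty")
        positions = np.concatenate(
            [
                rng.integers(lo, hi + 1, size=n_clustered),
                rng.integers(1, config.protein_length + 1, size=n - n_clustered),
            ]
        )
    else:
        positions = rng.integers(1, config.protein_length + 1, size=n)
    records = []
    for pos in positions:
        ref, alt = _random_substitution(rng)
        records.append(MutationRecord("PROT", "GENE", int(pos), ref, alt))
    return records


def simulate_alignment(config: FixtureConfig) -> AlignmentSet:
    """Generate an ungapped alignment with controlled per-position identity.

    The reference sequence is drawn uniformly over the 20 amino acids.
    Each non-reference sequence independently matches the reference at
    position p with probability ``identity_profile[p-1]`` (default 0.9
    everywhere, a typical ortholog identity), otherwise it carries a
    uniformly chosen different letter.  A nonzero ``gap_rate``
    additionally replaces non-reference characters with gaps at random.
    """
    if config.n_alignment_sequences < 2:
        raise ValueError("alignment needs at least 2 sequences")
    rng = np.random.default_rng([config.seed, 202])
    L = config.protein_length
    q = (
        np.full(L, 0.9)
        if config.identity_profile is None
        else np.asarray(config.identity_profile, dtype=float)
    )
    ref_idx = rng.integers(len(_AA), size=L)
    records = [("reference", "".join(_AA[ref_idx]))]
    for k in range(config.n_alignment_sequences - 1):
        match = rng.random(L) < q
        # mismatches: shift by a nonzero offset so the letter always differs
        offsets = rng.integers(1, len(_AA), size=L)
        idx = np.where(match, ref_idx, (ref_idx + offsets) % len(_AA))
        seq = _AA[idx]
        if config.gap_rate > 0.0:
            seq = np.where(rng.random(L) < config.gap_rate, "-", seq)
        records.append((f"ortholog_{k + 1}", "".join(seq)))
    return AlignmentSet(records=records, reference_id="reference")


# ---------------------------------------------------------------------------
# RET-like case fixture
# ---------------------------------------------------------------------------

#: the four domains of the worked RET example (1-based, inclusive)
RET_DOMAINS = (
    DomainAnnotation("Signal Peptide", 1, 24),
    DomainAnnotation("Cadherin", 191, 270),
    DomainAnnotation("Transmembrane", 636, 653),
    DomainAnnotation("Tyrosine Kinase", 724, 1005),
)

#: MEN2A-like hotspot: extracellular cysteines just before the
#: transmembrane start (the canonical cluster includes C634)
RET_CLUSTER_WINDOW = (600, 635)
_CLUSTER_CYSTEINES = (609, 611, 618, 620, 630, 634)
_CYS_SUBSTITUTIONS = ("R", "Y", "G", "S", "W", "F")

#: tyrosine-phosphosite-like PTM positions in the intracellular region
RET_PTM_SITES = (687, 696, 826, 900, 905, 981)


class RetLikeFixture(NamedTuple):
    mutations: list[MutationRecord]
    domains: tuple[DomainAnnotation, ...]
    ptms: tuple[PTMSite, ...]
    context: ProteinContext


def men2a_like_subset(mutations: Sequence[MutationRecord]) -> list[MutationRecord]:
    """The clustered cysteine mutations of a RET-like fixture: ref C
    inside the hotspot window (order preserved)."""
    lo, hi = RET_CLUSTER_WINDOW
    return [m for m in mutations if m.ref_aa == "C" and lo <= m.position <= hi]


def make_ret_like_fixture(
    length: int = 1114,
    n_mutations: int = 200,
    n_clustered: int = 24,
    seed: int = 7,
) -> RetLikeFixture:
    """Deterministic RET-like inputs: the four printed domains, PTM
    sites, and a mutation set mixing an even genome-wide background with
    a MEN2A-like cysteine cluster.

    Defaults follow the worked example: 200 disease mutations of which
    24 form the cluster.  ``length`` pads past the last domain end
    (1005) and is a parameter, not a constant.
    """
    if length < RET_DOMAINS[-1].end:
        raise ValueError(f"length must be >= {RET_DOMAINS[-1].end}")
    if n_clustered > n_mutations:
        raise ValueError("n_clustered cannot exceed n_mutations")
    rng = np.random.default_rng([seed, 303])

    records: list[MutationRecord] = []
    for _ in range(n_mutations - n_clustered):
        pos = int(rng.integers(1, length + 1))
        ref, alt = _random_substitution(rng)
        while ref == "C":  # keep the background out of the cysteine subset
            ref, alt = _random_substitution(rng)
        records.append(MutationRecord("RETLIKE", "RETLIKE", pos, ref, alt))
    for i in range(n_clustered):
        pos = _CLUSTER_CYSTEINES[int(rng.integers(len(_CLUSTER_CYSTEINES)))] if i else 634
        alt = _CYS_SUBSTITUTIONS[int(rng.integers(len(_CYS_SUBSTITUTIONS)))] if i else "R"
        records.append(MutationRecord("RETLIKE", "RETLIKE", pos, "C", alt))

    return RetLikeFixture(
        mutations=records,
        domains=RET_DOMAINS,
        ptms=tuple(PTMSite(p) for p in RET_PTM_SITES),
        context=ProteinContext(length=length, query_name="RET-like (synthetic)"),
    )
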
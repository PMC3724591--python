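"""Annotation of mutations against domains and PTM sites.

Mirrors the annotation table of the browser front-end: each mutation is
marked with the domains whose [start, end] interval contains it (both
ends inclusive), whether it falls exactly on a PTM site, and -- when a
conservation profile is available -- the conservation score at its
position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .conservation import ConservationProfile
from .io_formats import DomainAnnotation, MutationRecord, PTMSite


@dataclass(frozen=True)
class AnnotatedMutation:
    record: MutationRecord
    domains_hit: tuple[str, ...]
    is_ptm_site: bool
    conservation_score: Optional[float]


def annotate_mutations(
    mutations: Sequence[MutationRecord],
    domains: Sequence[DomainAnnotation],
    ptms: Sequence[PTMSite],
    profile: Optional[ConservationProfile] = None,
) -> list[AnnotatedMutation]:
    """Annotate each mutation; output order equals input order.

    Overlapping domains are all reported, in architecture-file order.
    The conservation score is attached only when a profile covering the
    position is supplied.
    """
    ptm_positions = {p.position for p in ptms}
    out = []
    for m in mutations:
        hits = tuple(d.name for d in domains if d.contains(m.position))
        score = None
        if profile is not None and 1 <= m.position <= len(profile):
            score = profile.score_at(m.position)
        out.append(
            AnnotatedMutation(
                record=m,
                domains_hit=hits,
                is_ptm_site=m.position in ptm_positions,
                conservation_score=score,
            )
        )
    return out


ANNOTATION_HEADER = (
    "protein", "gene", "position", "ref", "alt", "domains", "ptm_site",
    "conservation",
)


def write_annotation_table(
    annotated: Sequence[AnnotatedMutation], path: Union[str, Path]
) -> None:
    """Write the annotation TSV; one row per mutation, header always present.

    Domain hits are semicolon-joined ("none" when empty); ptm_site is
    yes/no; conservation is blank when no profile was supplied.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for a in annotated:
            m = a.record
            domains = ";".join(a.domains_hit) if a.domains_hit else "none"
            ptm = "yes" if a.is_ptm_site else "no"
            score = "" if a.conservation_score is None else f"{a.conservation_score:.6f}"
            fh.write(
                f"{m.protein_name}\t{m.gene_name}\t{m.position}\t{m.ref_aa}"
                f"\t{m.alt_aa}\t{domains}\t{ptm}\t{score}\n"
            )
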
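"""Reference-anchored conservation scoring of a multiple sequence alignment.

Every aligned sequence is compared to the user-designated reference at
each reference residue.  The per-position score is the exact-match
proportion

    s = n / t

where ``n`` is the number of non-reference sequences carrying the same
amino acid as the reference at that position and ``t`` is the total
number of non-reference sequences in the alignment.  ``s`` lies in
[0, 1]: 0 means no other sequence matches the reference there, 1 means
all of them do.  The reference row itself is excluded from both counts
(otherwise s could never reach 0), and ``t`` is constant across
positions, so a sequence gapped at a column counts as a mismatch there
rather than shrinking the denominator -- unaligned regions read as
poorly conserved, which is the visual intent of the track.

Alignment columns where the reference is gapped have no reference
coordinate and are dropped; :class:`ColumnMap` records the surviving
column for each 1-based reference residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union
from pathlib import Path

import numpy as np

from .io_formats import AlignmentSet

GAP = "-"


@dataclass(frozen=True)
class ColumnMap:
    """Map from 1-based reference residue index to 0-based alignment column.

    The domain is exactly 1..R where R is the number of non-gap
    characters in the reference row; the mapped columns are strictly
    increasing.
    """

    ref_position_to_column: dict[int, int]

    def __len__(self) -> int:
        return len(self.ref_position_to_column)

    def __getitem__(self, ref_position: int) -> int:
        return self.ref_position_to_column[ref_position]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-reference-position conservation: s = n/t plus the raw counts.

    All four arrays have length R (the reference non-gap count);
    index 0 corresponds to reference position 1.
    """

    scores: np.ndarray          # float in [0, 1]
    n_matches: np.ndarray       # int, 0 <= n <= t
    t_total: np.ndarray         # int, constant across positions
    ref_letters: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.scores)

    def score_at(self, position: int) -> float:
        """Score at a 1-based reference position."""
        if not 1 <= position <= len(self):
            raise IndexError(
                f"position {position} outside reference range 1..{len(self)}"
            )
        return float(self.scores[position - 1])


def build_column_map(alignment: AlignmentSet) -> ColumnMap:
    """One entry per non-gap reference character, in alignment order."""
    ref = alignment.reference_row
    mapping = {}
    pos = 0
    for col, ch in enumerate(ref):
        if ch != GAP:
            pos += 1
            mapping[pos] = col
    if not mapping:
        raise ValueError(
            f"reference row {alignment.reference_id!r} is entirely gaps"
        )
    return ColumnMap(mapping)


def conservation_scores(
    alignment: AlignmentSet,
    expected_length: Optional[int] = None,
) -> ConservationProfile:
    """Compute s = n/t for every reference position.

    Parameters
    ----------
    alignment:
        Aligned sequences including the reference row; at least one
        non-reference sequence is required.
    expected_length:
        If given (normally the protein length from the plot context),
        the reference non-gap count must equal it or a mismatch error
        is raised.
    """
    others = alignment.non_reference_rows()
    if not others:
        raise ValueError(
            "conservation requires at least one non-reference sequence"
        )
    cmap = build_column_map(alignment)
    if expected_length is not None and len(cmap) != expected_length:
        raise ValueError(
            f"reference row has {len(cmap)} residues but the protein context "
            f"declares length {expected_length}"
        )
    cols = np.fromiter(
        (cmap[p] for p in range(1, len(cmap) + 1)), dtype=np.intp, count=len(cmap)
    )
    matrix = np.frombuffer(
        "".join(seq for seq in others).encode("ascii"), dtype="S1"
    ).reshape(len(others), alignment.column_count)
    ref_row = np.frombuffer(alignment.reference_row.encode("ascii"), dtype="S1")
    ref_chars = ref_row[cols]
    n = (matrix[:, cols] == ref_chars[np.newaxis, :]).sum(axis=0)
    t = np.full(len(cmap), len(others), dtype=np.intp)
    return ConservationProfile(
        scores=n / t,
        n_matches=n.astype(np.intp),
        t_total=t,
        ref_letters=tuple(ref_chars.tobytes().decode("ascii")),
    )


def write_profile_tsv(
    profile: ConservationProfile, path: Union[str, Path]
) -> None:
    """Export the profile: position, ref_letter, n, t, score (one row each)."""
    with open(path, "w") as fh:
        fh.write("position\tref_letter\tn\tt\tscore\n")
        for i in range(len(profile)):
            fh.write(
                f"{i + 1}\t{profile.ref_letters[i]}\t{profile.n_matches[i]}"
                f"\t{profile.t_total[i]}\t{profile.scores[i]:.6f}\n"
            )
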
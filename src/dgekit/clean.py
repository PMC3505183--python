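"""Raw-to-clean tag filtering and library summaries.

A clean tag is a well-formed 21-mer (CATG anchor, ACGT alphabet) that is not
adaptor-derived, not flagged low-quality, and seen at least twice in the
library. The copy-number-1 filter runs last, so a malformed or adaptor tag
is attributed to its own rule rather than to the singleton rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from ._util import ANCHOR, TAG_LEN
from .simulate import ADAPTOR
from .types import TagLibrary

_VALID = set("ACGT")

#: Copy-number bins used for abundance distributions, chosen to expose both
#: the low-copy end (which dominates distinct tags) and the >100 class
#: (which dominates total tags) in deep libraries.
DEFAULT_BINS: list[tuple[int, Optional[int]]] = [
    (2, 5),
    (6, 10),
    (11, 20),
    (21, 50),
    (51, 100),
    (101, None),
]


def _well_formed(tag: str) -> bool:
    return (
        len(tag) == TAG_LEN
        and tag.startswith(ANCHOR)
        and set(tag) <= _VALID
    )


def extract_clean_tags(
    raw_library: TagLibrary,
    adaptor: str = ADAPTOR,
    quality_flags: Optional[dict[str, bool]] = None,
) -> TagLibrary:
    """Apply the cleaning rules to a raw library and return it with ``clean``
    populated (``raw`` is left untouched).

    Removed, in order: adaptor-equal or adaptor-prefixed tags; empty or
    whitespace tags; tags flagged low-quality; tags of length != 21, without
    the CATG anchor, or with non-ACGT symbols; finally tags with total copy
    number 1. An input where nothing survives yields an empty clean map with
    a warning, not an error.
    """
    if not raw_library.raw:
        raise ValueError("raw tag map is empty")
    flags = quality_flags or {}
    clean: dict[str, int] = {}
    for tag, count in raw_library.raw.items():
        if tag.startswith(adaptor):
            continue
        if not tag.strip() or tag.strip() != tag:
            continue
        if flags.get(tag, False) or tag in raw_library.low_quality:
            continue
        if not _well_formed(tag):
            continue
        clean[tag] = clean.get(tag, 0) + count
    clean = {t: c for t, c in clean.items() if c >= 2}
    if not clean:
        warnings.warn(
            f"no clean tags survive filtering in library {raw_library.library_id!r}",
            stacklevel=2,
        )
    return TagLibrary(
        library_id=raw_library.library_id,
        stage=raw_library.stage,
        strain=raw_library.strain,
        raw=dict(raw_library.raw),
        clean=clean,
        low_quality=set(raw_library.low_quality),
    )


@dataclass
class AbundanceBinCounts:
    bins: list[tuple[int, Optional[int]]]
    total_tags: list[int]
    distinct_tags: list[int]


def abundance_distribution(
    clean_library: TagLibrary,
    bins: Sequence[tuple[int, Optional[int]]] = tuple(DEFAULT_BINS),
) -> AbundanceBinCounts:
    """Per-bin (total tag, distinct tag) counts over copy-number ranges.

    ``bins`` must partition [2, inf): contiguous, non-overlapping, starting
    at 2, ending with an open-ended (hi=None) bin.
    """
    bins = [tuple(b) for b in bins]
    if not bins or bins[0][0] != 2 or bins[-1][1] is not None:
        raise ValueError("bins must start at 2 and end with an open-ended bin")
    for (lo, hi), (nlo, _) in zip(bins, bins[1:]):
        if hi is None or nlo != hi + 1:
            raise ValueError("bins must be contiguous and non-overlapping")
    total = [0] * len(bins)
    distinct = [0] * len(bins)
    for count in clean_library.clean.values():
        for k, (lo, hi) in enumerate(bins):
            if count >= lo and (hi is None or count <= hi):
                total[k] += count
                distinct[k] += 1
                break
    return AbundanceBinCounts(list(bins), total, distinct)


@dataclass
class LibrarySummary:
    library_id: str
    total_raw: int
    total_clean: int
    distinct_clean: int


def library_summary(clean_library: TagLibrary) -> LibrarySummary:
    return LibrarySummary(
        library_id=clean_library.library_id,
        total_raw=clean_library.total_raw,
        total_clean=clean_library.total_clean,
        distinct_clean=clean_library.distinct_clean,
    )
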
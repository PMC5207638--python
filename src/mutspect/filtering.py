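"""Quality filtering and repeat masking of multi-sample variant calls.

Records are retained only when every threshold is strictly exceeded: site
mapping quality MQ > 40, carrier genotype quality GQ > 20, site QUAL > 20,
carrier depth > 8, more than 2 carrier reads and more than 15% of carrier
reads supporting the alternate allele, and the site lies outside all repeat
mask intervals.  MQ and QUAL are site-level; GQ, depth and alt-read metrics
are evaluated in the strain(s) carrying the alternate allele (a pooled
variant of the alt-read rules is available as a config switch).

Coordinates are 1-based internally (VCF convention); mask intervals are
0-based half-open (BED convention) and converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: tally keys, in the order rules are checked (first failing rule wins)
FILTER_RULES: tuple[str, ...] = (
    "malformed", "mq", "gq", "qual", "depth",
    "alt_reads", "alt_fraction", "masked",
)


@dataclass(eq=False)
class VariantRecord:
    """One called variant with per-strain genotypes and quality metrics.

    ``gt`` marks the strains carrying at least one alternate allele
    (presence, not dosage); ``gq``/``dp``/``alt_reads`` are aligned with
    ``strains``.  ``alt`` may be a comma-joined string when the caller
    reported several alternate alleles; such records are diverted by
    :func:`split_snps_indels`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    mq: float
    strains: tuple[str, ...]
    gt: np.ndarray
    gq: np.ndarray
    dp: np.ndarray
    alt_reads: np.ndarray
    malformed: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        self.gt = np.asarray(self.gt, dtype=bool)
        self.gq = np.asarray(self.gq, dtype=float)
        self.dp = np.asarray(self.dp, dtype=float)
        self.alt_reads = np.asarray(self.alt_reads, dtype=float)

    @property
    def carriers(self) -> tuple[str, ...]:
        return tuple(s for s, g in zip(self.strains, self.gt) if g)

    @property
    def n_carriers(self) -> int:
        return int(self.gt.sum())

    @property
    def is_multiallelic(self) -> bool:
        return "," in self.alt

    @property
    def is_snp(self) -> bool:
        return (
            not self.is_multiallelic
            and len(self.ref) == 1 and len(self.alt) == 1
            and self.ref in "ACGT" and self.alt in "ACGT"
        )

    @property
    def is_indel(self) -> bool:
        return not self.is_multiallelic and len(self.ref) != len(self.alt)


class IntervalMask:
    """Repeat-mask lookup over 0-based half-open intervals.

    A 1-based position ``p`` is masked iff ``start < p <= end`` for some
    interval on its chromosome, i.e. ``start <= p-1 < end`` in 0-based
    coordinates.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(
                    f"mask interval with end <= start: {chrom}:{start}-{end}"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            self._starts[chrom] = np.array([s for s, _ in ivals])
            self._ends[chrom] = np.array([e for _, e in ivals])

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self._starts:
            return False
        starts = self._starts[chrom]
        i = int(np.searchsorted(starts, pos - 1, side="right")) - 1
        return i >= 0 and pos - 1 < self._ends[chrom][i]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds (all strict inequalities) and mask for variant filtering."""

    min_mq: float = 40.0
    min_gq: float = 20.0
    min_qual: float = 20.0
    min_depth: float = 8.0
    min_alt_reads: float = 2.0
    min_alt_fraction: float = 0.15
    mask_intervals: tuple[tuple[str, int, int], ...] = ()
    #: evaluate alt-read count/fraction on reads pooled over carriers rather
    #: than requiring every carrier strain to pass individually
    pooled_alt_reads: bool = False

    def __post_init__(self):
        for name in ("min_mq", "min_gq", "min_qual", "min_depth",
                     "min_alt_reads", "min_alt_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for chrom, start, end in self.mask_intervals:
            if end <= start:
                raise ValueError(
                    f"mask interval with end <= start: {chrom}:{start}-{end}"
                )


def first_failing_rule(
    record: VariantRecord, config: FilterConfig, mask: IntervalMask
) -> str | None:
    """The first rule ``record`` fails, or None if it passes all of them."""
    if record.malformed:
        return "malformed"
    try:
        if not np.isfinite(record.mq) or not np.isfinite(record.qual):
            return "malformed"
        if record.mq <= config.min_mq:
            return "mq"
        carriers = record.gt
        if carriers.any():
            gq, dp, ar = (record.gq[carriers], record.dp[carriers],
                          record.alt_reads[carriers])
            if not (np.isfinite(gq).all() and np.isfinite(dp).all()
                    and np.isfinite(ar).all()):
                return "malformed"
            if not (gq > config.min_gq).all():
                return "gq"
            if record.qual <= config.min_qual:
                return "qual"
            if not (dp > config.min_depth).all():
                return "depth"
            if config.pooled_alt_reads:
                if ar.sum() <= config.min_alt_reads:
                    return "alt_reads"
                if ar.sum() <= config.min_alt_fraction * dp.sum():
                    return "alt_fraction"
            else:
                if not (ar > config.min_alt_reads).all():
                    return "alt_reads"
                if not (ar > config.min_alt_fraction * dp).all():
                    return "alt_fraction"
        elif record.qual <= config.min_qual:
            return "qual"
        if mask.contains(record.chrom, record.pos):
            return "masked"
    except (TypeError, IndexError, FloatingPointError):
        logger.warning(
            "malformed genotype fields at %s:%d", record.chrom, record.pos
        )
        return "malformed"
    return None


def apply_filters(
    records: Iterable[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply all quality filters and the repeat mask.

    Returns the retained records and a tally of rejections keyed by the
    first failing rule (a record may fail several; only the first is
    counted, so |retained| + sum(tally) = |input|).
    """
    mask = IntervalMask(config.mask_intervals)
    tally = {rule: 0 for rule in FILTER_RULES}
    kept = []
    for record in records:
        rule = first_failing_rule(record, config, mask)
        if rule is None:
            kept.append(record)
        else:
            tally[rule] += 1
    return kept, tally


def mask_repeats(
    records: Iterable[VariantRecord],
    intervals: Iterable[tuple[str, int, int]],
) -> list[VariantRecord]:
    """Records whose position falls outside all (0-based half-open) intervals."""
    mask = IntervalMask(intervals)
    return [r for r in records if not mask.contains(r.chrom, r.pos)]


def split_snps_indels(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord]]:
    """Partition records into biallelic SNPs, indels, and discarded records.

    A site is discarded as multiallelic when more than one distinct
    alternate allele is observed across the sample (whether as a
    multi-ALT record or as several records at one position); equal-length
    multi-base substitutions are also diverted to the discard list.
    """
    alts_at_site: dict[tuple[str, int], set[str]] = {}
    for r in records:
        alts_at_site.setdefault((r.chrom, r.pos), set()).update(
            r.alt.split(",")
        )
    snps: list[VariantRecord] = []
    indels: list[VariantRecord] = []
    discarded: list[VariantRecord] = []
    for r in records:
        if r.is_multiallelic or len(alts_at_site[(r.chrom, r.pos)]) > 1:
            discarded.append(r)
        elif r.is_snp:
            snps.append(r)
        elif r.is_indel:
            indels.append(r)
        else:
            discarded.append(r)
    return snps, indels, discarded


def corrupted(record: VariantRecord, **updates) -> VariantRecord:
    """A copy of ``record`` with fields replaced (test fixture helper)."""
    return replace(record, **updates)
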
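"""Singleton-indel aging and flank characterisation.

Indels are left-normalised (shifted to their leftmost equivalent
representation) before any positional analysis; un-normalised calls
double-count events adjacent to simple repeats.  The anchor of a normalised
indel is the first affected reference base: the first deleted base for a
deletion, the base immediately right of the insertion point for an
insertion.  Flanks are the 10 reference bases on either side of the affected
run, read 5'->3' on the reference strand.

Aging follows the same per-(strain, chromosome) density rule as SNP
singletons, but on the indel ledger alone, so indel ages are densities of
indel singletons only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aging import AgeBin, _density_ages, bin_by_age
from .filtering import VariantRecord
from .spectrum import EffectClassifier

logger = logging.getLogger(__name__)

FLANK_BP = 10


def left_normalize(
    seq: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Leftmost VCF representation of an indel on reference ``seq``.

    ``pos`` is 1-based; the returned record keeps the VCF anchored form
    (first base of ref and alt equal for pure insertions/deletions).

    >>> left_normalize("GAAAAC", 4, "AA", "A")
    (1, 'GA', 'G')
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref[-1] == alt[-1] and pos > 1:
        prev = seq[pos - 2]
        ref, alt = prev + ref[:-1], prev + alt[:-1]
        pos -= 1
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class IndelRecord:
    """A left-normalised singleton indel with flanks and density age.

    ``length`` is signed (+bp insertion, -bp deletion); ``anchor`` is the
    1-based first affected reference base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    carrier: str
    length: int
    anchor: int
    flank_5p: str
    flank_3p: str
    age: float | None = None

    def __post_init__(self):
        if abs(self.length) < 1:
            raise ValueError("indel length must be at least 1 bp")


def from_variant(
    record: VariantRecord, carrier: str, genome: Mapping[str, str],
    flank: int = FLANK_BP,
) -> IndelRecord | None:
    """Build an :class:`IndelRecord` from a VCF-style record, or None when
    the indel sits within ``flank`` bp of a contig end."""
    seq = genome[record.chrom]
    pos, ref, alt = left_normalize(seq, record.pos, record.ref, record.alt)
    length = len(alt) - len(ref)
    anchor = pos + 1
    if length < 0:  # deletion: run spans pos+1 .. pos+|length|
        run_end = pos + len(ref) - 1
    else:  # insertion after pos
        run_end = pos
    if pos - flank < 0 or run_end + flank > len(seq):
        return None
    flank_5p = seq[pos - flank:pos]
    flank_3p = seq[run_end:run_end + flank]
    return IndelRecord(
        chrom=record.chrom, pos=pos, ref=ref, alt=alt, carrier=carrier,
        length=length, anchor=anchor, flank_5p=flank_5p, flank_3p=flank_3p,
    )


def build_indel_records(
    records: Sequence[VariantRecord], genome: Mapping[str, str],
    flank: int = FLANK_BP,
) -> tuple[list[IndelRecord], int]:
    """Singleton indels with flanks; returns (records, n_dropped_near_edge)."""
    out: list[IndelRecord] = []
    n_dropped = 0
    for r in records:
        if r.n_carriers != 1:
            continue
        rec = from_variant(r, r.carriers[0], genome, flank=flank)
        if rec is None:
            n_dropped += 1
        else:
            out.append(rec)
    if n_dropped:
        logger.info("dropped %d indels within %d bp of a contig end",
                    n_dropped, flank)
    return out, n_dropped


def age_indels(
    indels: Sequence[IndelRecord],
    chromosome_lengths: Mapping[str, int],
    pooled: bool = False,
) -> list[IndelRecord]:
    """Density ages for indel singletons (same rule as SNPs, separate ledger)."""
    ages = _density_ages(
        indels, chromosome_lengths,
        get_chrom=lambda r: r.chrom, get_carrier=lambda r: r.carrier,
        pooled=pooled,
    )
    return [replace(r, age=a) for r, a in zip(indels, ages)]


def flank_base_composition(indels: Sequence[IndelRecord]) -> pd.DataFrame:
    """A/C/G/T fractions at each flank offset (-10..-1, +1..+10).

    Offset -1 is the base immediately 5' of the affected run, +1 immediately
    3'; each offset's four fractions sum to one.
    """
    offsets = list(range(-FLANK_BP, 0)) + list(range(1, FLANK_BP + 1))
    counts = {off: {b: 0 for b in "ACGT"} for off in offsets}
    for rec in indels:
        for i, base in enumerate(rec.flank_5p):  # left->right = -10..-1
            counts[i - FLANK_BP][base] += 1
        for i, base in enumerate(rec.flank_3p):
            counts[i + 1][base] += 1
    n = len(indels)
    data = {
        b: [counts[off][b] / n if n else np.nan for off in offsets]
        for b in "ACGT"
    }
    return pd.DataFrame(data, index=pd.Index(offsets, name="offset"))


def _adjacent_run(flank: str, from_start: bool) -> tuple[str, int]:
    """(base, length) of the homopolymer run touching the indel boundary."""
    s = flank if from_start else flank[::-1]
    if not s:
        return "", 0
    base = s[0]
    run = 1
    while run < len(s) and s[run] == base:
        run += 1
    return base, run


def str_adjacency(
    indels: Sequence[IndelRecord],
    max_len: int = FLANK_BP,
    mode: str = "touching",
) -> pd.DataFrame:
    """Fraction of indels flanked by a single-base repeat run >= m, per base.

    ``touching`` (the headline statistic): the run must be immediately
    adjacent to the indel boundary (a suffix of the 5' flank or a prefix of
    the 3' flank).  ``window``: a run anywhere within the +/-10 bp window
    counts.  Fractions are cumulative in m and therefore nonincreasing.
    """
    n = len(indels)
    best: dict[str, np.ndarray] = {b: np.zeros(n, dtype=int) for b in "ACGT"}
    for i, rec in enumerate(indels):
        if mode == "touching":
            for flank, from_start in ((rec.flank_5p, False), (rec.flank_3p, True)):
                base, run = _adjacent_run(flank, from_start)
                if base:
                    best[base][i] = max(best[base][i], run)
        elif mode == "window":
            for flank in (rec.flank_5p, rec.flank_3p):
                j = 0
                while j < len(flank):
                    base = flank[j]
                    run = 1
                    while j + run < len(flank) and flank[j + run] == base:
                        run += 1
                    best[base][i] = max(best[base][i], run)
                    j += run
        else:
            raise ValueError(f"unknown mode {mode!r}")
    data = {
        b: [float((best[b] >= m).mean()) if n else np.nan
            for m in range(1, max_len + 1)]
        for b in "ACGT"
    }
    return pd.DataFrame(data, index=pd.RangeIndex(1, max_len + 1, name="m"))


def coding_fraction_by_age(
    indels: Sequence[IndelRecord],
    classifier: EffectClassifier,
    age_edges: Sequence[float] | None = None,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Fraction of indels whose anchor lies in a coding interval, per age bin.

    Bins come from fixed ``age_edges`` (e.g. ``[0.002, ...]`` to reproduce a
    young indel class) when given, otherwise from ``n_bins`` equal-count
    bins.  The standard error is binomial, sqrt(p(1-p)/n); empty bins are
    reported with NaN fraction rather than dropped.
    """
    if any(r.age is None for r in indels):
        raise ValueError("indels must be aged first")
    if age_edges is not None:
        edges = [0.0, *sorted(age_edges), np.inf]
        bins = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            members = [r for r in indels if lo <= r.age < hi]
            bins.append(AgeBin(
                label=f"[{lo:.4g},{hi:.4g})", low=lo, high=hi, members=members
            ))
    else:
        bins = bin_by_age(indels, n_bins)
    rows = []
    for b in bins:
        n = len(b.members)
        n_coding = sum(
            classifier.coding_interval(r.chrom, r.anchor) is not None
            for r in b.members
        )
        if n:
            p = n_coding / n
            se = float(np.sqrt(p * (1 - p) / n))
        else:
            p = se = np.nan
        rows.append(
            {"bin": b.label, "low": b.low, "high": b.high,
             "n": n, "n_coding": n_coding, "coding_fraction": p, "se": se}
        )
    return pd.DataFrame(rows)


def indels_to_frame(indels: Sequence[IndelRecord]) -> pd.DataFrame:
    """Tidy table of indel records."""
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
             "carrier": r.carrier, "length": r.length, "anchor": r.anchor,
             "flank_5p": r.flank_5p, "flank_3p": r.flank_3p, "age": r.age}
            for r in indels
        ],
        columns=["chrom", "pos", "ref", "alt", "carrier", "length",
                 "anchor", "flank_5p", "flank_3p", "age"],
    )
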
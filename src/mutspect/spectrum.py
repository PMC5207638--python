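"""Selection signatures and mutational-spectrum statistics.

This module computes, for any set of single-nucleotide variants (a population
frequency class, an age bin of singletons, or a whole call set):

* the three classical selection signatures —
  %Pn   : fraction of coding changes that are nonsynonymous
          (neutral expectation ~0.75 under the standard genetic code),
  Ts/Tv : transitions (A<->G, C<->T) over transversions
          (~1 for raw spontaneous mutations, >2.5 in divergence data),
  GCeqm : the equilibrium GC percentage implied by the opposing per-site
          mutational fluxes, 100*v/(u+v), where v is the per-AT-site rate
          toward G:C and u the per-GC-site rate toward A:T;

* relative mutation rates for the six strand-collapsed nucleotide changes
  and for the 32 triplet neighbour environments (5' base x focal pyrimidine
  x 3' base), each normalised by the number of eligible sites in the
  analysed (unmasked) genome;

* two-proportion Z-tests with Bonferroni correction for comparing rate
  tables, and seeded bootstrap standard errors.

Strand collapse reports every change by its pyrimidine source: a G->A call
on the reference strand is counted as C->T, and a triplet whose focal base
is a purine is reverse-complemented before lookup.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table as _STANDARD_TABLE
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# genetic code and strand collapse
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: the six strand-collapsed change classes, keyed by pyrimidine source
CLASSES6: tuple[str, ...] = ("C>T", "C>A", "C>G", "T>C", "T>A", "T>G")

#: the 32 neighbour environments: 5' base + focal pyrimidine + 3' base
CONTEXTS32: tuple[str, ...] = tuple(
    f"{five}{focal}{three}"
    for focal in "CT"
    for five in "ACGT"
    for three in "ACGT"
)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)
CODON_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_AA.update({c: "*" for c in STOP_CODONS})

EFFECTS = ("synonymous", "nonsynonymous", "nonsense", "noncoding")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def collapse_change(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base change, keyed by pyrimidine.

    >>> collapse_change("G", "A")
    'C>T'
    """
    if ref in "CT":
        return f"{ref}>{alt}"
    return f"{complement(ref)}>{complement(alt)}"


def collapse_context(triplet: str) -> str:
    """Collapse a reference triplet so its focal (middle) base is a pyrimidine."""
    if triplet[1] in "CT":
        return triplet
    return revcomp(triplet)


def is_transition(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "G"}, {"C", "T"})


class UndefinedStatisticError(ValueError):
    """A statistic has an empty or zero denominator on the given data."""


class AnnotationError(ValueError):
    """The coding annotation is inconsistent (e.g. interval length not a
    multiple of three, or disagreement with the reference sequence)."""


class BootstrapError(RuntimeError):
    """The statistic was undefined on too many bootstrap resamples."""


# ---------------------------------------------------------------------------
# coding-effect classification
# ---------------------------------------------------------------------------

class EffectClassifier:
    """Classify SNPs as synonymous / nonsynonymous / nonsense / noncoding.

    The codon containing each site is read on the annotated coding strand and
    translated with the standard genetic code.  ``annotation`` is a DataFrame
    with columns ``chrom``, ``start``, ``end`` (1-based inclusive) and
    ``strand``; every interval must be a multiple of 3 bp long.  When
    intervals overlap, the first one in annotation order wins (logged once).

    A reference codon that is itself a stop codon (the terminal codon of a
    gene) is treated as follows: a change to another stop codon is
    synonymous, any other change (stop loss) is nonsynonymous.
    """

    def __init__(self, genome: Mapping[str, str], annotation: pd.DataFrame):
        self._genome = genome
        self._rows: dict[str, list[tuple[int, int, str]]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._overlapping: dict[str, bool] = {}
        for chrom, sub in annotation.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any((ends - starts + 1) % 3 != 0):
                raise AnnotationError(
                    f"coding interval length not a multiple of 3 on {chrom}"
                )
            overlapping = bool(np.any(starts[1:] <= ends[:-1]))
            if overlapping:
                logger.warning(
                    "overlapping coding intervals on %s; first annotation wins",
                    chrom,
                )
            self._overlapping[chrom] = overlapping
            self._rows[chrom] = list(
                zip(starts.tolist(), ends.tolist(), sub["strand"].tolist())
            )
            self._starts[chrom] = starts
            self._ends[chrom] = ends

    def coding_interval(self, chrom: str, pos: int) -> tuple[int, int, str] | None:
        """The (start, end, strand) of the coding interval containing ``pos``,
        or None for noncoding sites."""
        if chrom not in self._starts:
            return None
        if self._overlapping[chrom]:
            for row in self._rows[chrom]:
                if row[0] <= pos <= row[1]:
                    return row
            return None
        starts = self._starts[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0:
            return None
        row = self._rows[chrom][i]
        return row if pos <= row[1] else None

    def classify(self, chrom: str, pos: int, ref: str, alt: str) -> str:
        interval = self.coding_interval(chrom, pos)
        if interval is None:
            return "noncoding"
        start, end, strand = interval
        seq = self._genome[chrom]
        if strand == "+":
            offset = pos - start
        else:
            offset = end - pos
        codon_i, within = divmod(offset, 3)
        if strand == "+":
            lo = start - 1 + 3 * codon_i
            codon = seq[lo:lo + 3]
            ref_cs, alt_cs = ref, alt
        else:
            hi = end - 3 * codon_i
            codon = revcomp(seq[hi - 3:hi])
            ref_cs, alt_cs = complement(ref), complement(alt)
        if codon[within] != ref_cs:
            raise AnnotationError(
                f"reference allele {ref} at {chrom}:{pos} disagrees with the "
                f"reference sequence codon {codon}"
            )
        alt_codon = codon[:within] + alt_cs + codon[within + 1:]
        aa_ref, aa_alt = CODON_AA[codon], CODON_AA[alt_codon]
        if aa_ref == "*":
            return "synonymous" if aa_alt == "*" else "nonsynonymous"
        if aa_alt == "*":
            return "nonsense"
        return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def classify_coding_effect(
    chrom: str, pos: int, ref: str, alt: str,
    annotation: pd.DataFrame, genome: Mapping[str, str],
) -> str:
    """One-shot wrapper around :class:`EffectClassifier` for a single SNP."""
    return EffectClassifier(genome, annotation).classify(chrom, pos, ref, alt)


def neutral_pn_expectation(convention: str = "exclude_nonsense") -> float:
    """Expected %Pn in the absence of selection.

    Enumerates all 61 x 9 = 549 single-base codon changes at equal codon
    frequency and equal per-change probability and returns the nonsynonymous
    fraction under ``convention``:

    * ``exclude_nonsense`` — stop-gaining changes removed from numerator and
      denominator (392/526 ~ 0.75);
    * ``nonsense_as_nonsyn`` — stop gains counted as nonsynonymous
      (415/549 ~ 0.76).
    """
    n_syn = n_non = n_stop = 0
    for codon in SENSE_CODONS:
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                alt_codon = codon[:i] + b + codon[i + 1:]
                aa = CODON_AA[alt_codon]
                if aa == "*":
                    n_stop += 1
                elif aa == CODON_AA[codon]:
                    n_syn += 1
                else:
                    n_non += 1
    if convention == "exclude_nonsense":
        return n_non / (n_non + n_syn)
    if convention == "nonsense_as_nonsyn":
        return (n_non + n_stop) / (n_non + n_syn + n_stop)
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# variant-frame annotation
# ---------------------------------------------------------------------------

def annotate_snp_frame(
    df: pd.DataFrame,
    genome: Mapping[str, str] | None = None,
    classifier: EffectClassifier | None = None,
) -> pd.DataFrame:
    """Add derived columns to a SNP frame with chrom/pos/ref/alt.

    Adds ``mut_class`` (strand-collapsed 6-class key), ``transition`` (bool),
    ``gc_dir`` (``to_gc`` / ``to_at`` / ``conservative``), and, when a genome
    and/or classifier is supplied, ``context`` (collapsed reference triplet,
    NaN at contig edges) and ``effect``.
    """
    out = df.copy()
    out["mut_class"] = [
        collapse_change(r, a) for r, a in zip(out["ref"], out["alt"])
    ]
    out["transition"] = [
        is_transition(r, a) for r, a in zip(out["ref"], out["alt"])
    ]
    gc_dir = {
        "T>C": "to_gc", "T>G": "to_gc",
        "C>T": "to_at", "C>A": "to_at",
        "C>G": "conservative", "T>A": "conservative",
    }
    out["gc_dir"] = out["mut_class"].map(gc_dir)
    if genome is not None:
        contexts = []
        for chrom, pos in zip(out["chrom"], out["pos"]):
            seq = genome[chrom]
            if pos < 2 or pos > len(seq) - 1:
                contexts.append(np.nan)
            else:
                contexts.append(collapse_context(seq[pos - 2:pos + 1]))
        out["context"] = contexts
    if classifier is not None:
        out["effect"] = [
            classifier.classify(c, p, r, a)
            for c, p, r, a in zip(out["chrom"], out["pos"], out["ref"], out["alt"])
        ]
    return out


# ---------------------------------------------------------------------------
# the three selection signatures
# ---------------------------------------------------------------------------

def percent_nonsynonymous(
    df: pd.DataFrame, convention: str = "exclude_nonsense"
) -> float:
    """%Pn = nonsynonymous / (nonsynonymous + synonymous) among coding SNPs.

    Under the default convention nonsense changes are excluded from both
    counts; under ``nonsense_as_nonsyn`` they join the numerator.
    """
    effects = df["effect"]
    n_non = int((effects == "nonsynonymous").sum())
    n_syn = int((effects == "synonymous").sum())
    n_stop = int((effects == "nonsense").sum())
    if convention == "nonsense_as_nonsyn":
        n_non += n_stop
    elif convention != "exclude_nonsense":
        raise ValueError(f"unknown convention {convention!r}")
    denom = n_non + n_syn
    if denom == 0:
        raise UndefinedStatisticError("no coding variants; %Pn undefined")
    return n_non / denom


def ts_tv_ratio(df: pd.DataFrame) -> float:
    """Transitions over transversions; raises when no transversion is present."""
    if "transition" in df.columns:
        ts_mask = df["transition"].to_numpy(dtype=bool)
    else:
        ts_mask = np.array(
            [is_transition(r, a) for r, a in zip(df["ref"], df["alt"])], dtype=bool
        )
    n_ts = int(ts_mask.sum())
    n_tv = int(len(ts_mask) - n_ts)
    if n_tv == 0:
        raise UndefinedStatisticError("no transversions; Ts/Tv undefined")
    return n_ts / n_tv


def gc_equilibrium(df: pd.DataFrame, at_sites: int, gc_sites: int) -> float:
    """Equilibrium GC percentage 100*v/(u+v).

    v is the per-site rate toward G:C, (#AT->GC changes)/at_sites; u is the
    per-site rate toward A:T, (#GC->AT changes)/gc_sites.  GC-conservative
    changes (C<->G, A<->T) are ignored.
    """
    if at_sites <= 0 or gc_sites <= 0:
        raise UndefinedStatisticError("site counts must be positive")
    if "gc_dir" in df.columns:
        gc_dir = df["gc_dir"]
    else:
        gc_dir = annotate_snp_frame(df)["gc_dir"]
    v = int((gc_dir == "to_gc").sum()) / at_sites
    u = int((gc_dir == "to_at").sum()) / gc_sites
    if u + v == 0:
        raise UndefinedStatisticError("no GC-changing mutations; GCeqm undefined")
    return 100.0 * v / (u + v)


def bootstrap_se(
    df: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    n_boot: int = 500,
    seed: int = 0,
    max_undefined_frac: float = 0.10,
) -> float:
    """Bootstrap standard error of ``statistic`` over variant resamples.

    Variants (rows) are resampled with replacement ``n_boot`` times with a
    seeded generator; the SE is the standard deviation of the statistic over
    the resamples.  Resamples on which the statistic is undefined are skipped;
    if more than ``max_undefined_frac`` of them fail, a
    :class:`BootstrapError` is raised with the failure count.
    """
    rng = np.random.default_rng(seed)
    n = len(df)
    if n == 0:
        raise UndefinedStatisticError("cannot bootstrap an empty set")
    values = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            values.append(statistic(df.iloc[idx]))
        except UndefinedStatisticError:
            n_failed += 1
    if n_failed > max_undefined_frac * n_boot:
        raise BootstrapError(
            f"statistic undefined on {n_failed}/{n_boot} bootstrap resamples"
        )
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


# ---------------------------------------------------------------------------
# analysed-genome site counts
# ---------------------------------------------------------------------------

def _analyzed_mask(
    seq_len: int, chrom: str, mask_intervals: Iterable[tuple[str, int, int]] | None
) -> np.ndarray:
    keep = np.ones(seq_len, dtype=bool)
    if mask_intervals:
        for c, start, end in mask_intervals:
            if c == chrom:
                keep[start:end] = False
    return keep


def base_counts(
    genome: Mapping[str, str],
    mask_intervals: Iterable[tuple[str, int, int]] | None = None,
) -> dict[str, int]:
    """A/C/G/T counts over the analysed genome (masked intervals excluded;
    mask intervals are 0-based half-open)."""
    counts = {b: 0 for b in "ACGT"}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        keep = _analyzed_mask(len(seq), chrom, mask_intervals)
        for b in "ACGT":
            counts[b] += int(np.sum((arr == ord(b)) & keep))
    return counts


def at_gc_site_counts(
    genome: Mapping[str, str],
    mask_intervals: Iterable[tuple[str, int, int]] | None = None,
) -> tuple[int, int]:
    """(#A/T sites, #G/C sites) over the analysed genome."""
    c = base_counts(genome, mask_intervals)
    return c["A"] + c["T"], c["C"] + c["G"]


def context_site_counts(
    genome: Mapping[str, str],
    mask_intervals: Iterable[tuple[str, int, int]] | None = None,
) -> dict[str, int]:
    """Occurrences of each of the 32 collapsed triplet environments.

    A triplet is counted when its central site is analysed; the two
    single-base contig ends have no full triplet and are skipped.
    """
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    idx_of = {t: i for i, t in enumerate(CONTEXTS32)}
    collapse_map = np.empty(64, dtype=np.int8)
    for i, trip in enumerate(
        "".join(p) for p in itertools.product("ACGT", repeat=3)
    ):
        collapse_map[i] = idx_of[collapse_context(trip)]
    totals = np.zeros(32, dtype=np.int64)
    for chrom, seq in genome.items():
        if len(seq) < 3:
            continue
        arr = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        trip_codes = arr[:-2] * 16 + arr[1:-1] * 4 + arr[2:]
        keep = _analyzed_mask(len(seq), chrom, mask_intervals)[1:-1]
        keep &= trip_codes >= 0
        totals += np.bincount(
            collapse_map[trip_codes[keep]], minlength=32
        )
    return {t: int(totals[i]) for i, t in enumerate(CONTEXTS32)}


# ---------------------------------------------------------------------------
# relative rate tables
# ---------------------------------------------------------------------------

def _rate_table(
    counts: np.ndarray, sites: np.ndarray, keys: Sequence[str],
    n_boot: int, seed: int,
) -> pd.DataFrame:
    if np.any((sites == 0) & (counts > 0)):
        raise AnnotationError(
            "mutations observed in a class with zero eligible sites"
        )
    per_site = np.divide(
        counts, sites, out=np.zeros(len(keys), dtype=float), where=sites > 0
    )
    total = per_site.sum()
    if total == 0:
        raise UndefinedStatisticError("no mutations; rate table undefined")
    rates = per_site / total
    n = int(counts.sum())
    # bootstrap over variants: since the statistic depends on the data only
    # through class counts, resampling rows with replacement is a multinomial
    # redraw of the counts
    rng = np.random.default_rng(seed)
    if n_boot > 0 and n > 0:
        boot_counts = rng.multinomial(n, counts / n, size=n_boot)
        boot_ps = np.divide(
            boot_counts, sites[None, :],
            out=np.zeros_like(boot_counts, dtype=float),
            where=sites[None, :] > 0,
        )
        boot_rates = boot_ps / boot_ps.sum(axis=1, keepdims=True)
        se = boot_rates.std(axis=0, ddof=1)
    else:
        se = np.zeros(len(keys))
    return pd.DataFrame(
        {"count": counts, "sites": sites, "rate": rates, "se": se},
        index=pd.Index(keys, name="class"),
    )


def relative_rates_6class(
    df: pd.DataFrame,
    genome: Mapping[str, str],
    mask_intervals: Iterable[tuple[str, int, int]] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative rates of the six strand-collapsed changes.

    Each class rate is (mutation count) / (eligible source sites in the
    analysed genome), normalised so the six rates sum to one.  C-source
    classes are eligible at C or G sites, T-source classes at T or A sites.
    """
    ann = df if "mut_class" in df.columns else annotate_snp_frame(df)
    counts = np.array(
        [int((ann["mut_class"] == k).sum()) for k in CLASSES6], dtype=np.int64
    )
    at_sites, gc_sites = at_gc_site_counts(genome, mask_intervals)
    sites = np.array(
        [gc_sites if k[0] == "C" else at_sites for k in CLASSES6], dtype=np.int64
    )
    return _rate_table(counts, sites, CLASSES6, n_boot, seed)


def context_rates_32(
    df: pd.DataFrame,
    genome: Mapping[str, str],
    mask_intervals: Iterable[tuple[str, int, int]] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative rates of the 32 neighbour environments.

    All changes from a focal base are pooled per environment; each
    environment's rate is normalised by its genomic occurrence count in the
    analysed region.  Variants at contig edges (no full triplet) are dropped.
    """
    ann = df if "context" in df.columns else annotate_snp_frame(df, genome=genome)
    ctx = ann["context"].dropna()
    counts = np.array(
        [int((ctx == t).sum()) for t in CONTEXTS32], dtype=np.int64
    )
    site_map = context_site_counts(genome, mask_intervals)
    sites = np.array([site_map[t] for t in CONTEXTS32], dtype=np.int64)
    return _rate_table(counts, sites, CONTEXTS32, n_boot, seed)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_rates(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-class two-proportion Z-tests between two rate tables.

    For each class the proportion of dataset A's mutations in that class is
    tested against dataset B's with a pooled two-proportion Z-test; p-values
    are Bonferroni-adjusted by the number of classes compared.
    """
    if list(table_a.index) != list(table_b.index):
        raise ValueError("rate tables have mismatched class keys")
    n_a = int(table_a["count"].sum())
    n_b = int(table_b["count"].sum())
    m = len(table_a)
    rows = []
    for key in table_a.index:
        c_a = int(table_a.loc[key, "count"])
        c_b = int(table_b.loc[key, "count"])
        if c_a + c_b == 0 or c_a + c_b == n_a + n_b:
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest([c_a, c_b], [n_a, n_b])
        p_adj = min(1.0, m * p)
        rows.append(
            {"class": key, "z": float(z), "p": float(p),
             "p_adj": p_adj, "stars": _stars(p_adj)}
        )
    return pd.DataFrame(rows).set_index("class")


# ---------------------------------------------------------------------------
# per-bin signature summaries
# ---------------------------------------------------------------------------

@dataclass
class SelectionSignature:
    """The (%Pn, Ts/Tv, GCeqm) triple with bootstrap SEs for one variant set.

    Undefined cells (e.g. no coding variant in a small bin) are NaN rather
    than dropped.
    """

    label: str
    n_variants: int
    pn: float
    pn_se: float
    ts_tv: float
    ts_tv_se: float
    gc_eqm: float
    gc_eqm_se: float


def signature_for(
    df: pd.DataFrame,
    at_sites: int,
    gc_sites: int,
    label: str = "",
    convention: str = "exclude_nonsense",
    n_boot: int = 500,
    seed: int = 0,
) -> SelectionSignature:
    """Compute one :class:`SelectionSignature` for an annotated SNP frame
    (columns ``effect``, ``transition``, ``gc_dir`` required)."""

    def guarded(stat, boot_seed):
        try:
            value = stat(df)
        except UndefinedStatisticError:
            return np.nan, np.nan
        try:
            se = bootstrap_se(df, stat, n_boot=n_boot, seed=boot_seed)
        except (BootstrapError, UndefinedStatisticError):
            se = np.nan
        return value, se

    pn, pn_se = guarded(
        lambda d: percent_nonsynonymous(d, convention=convention), seed
    )
    tstv, tstv_se = guarded(ts_tv_ratio, seed + 1)
    gceq, gceq_se = guarded(
        lambda d: gc_equilibrium(d, at_sites, gc_sites), seed + 2
    )
    return SelectionSignature(
        label=label, n_variants=len(df),
        pn=pn, pn_se=pn_se,
        ts_tv=tstv, ts_tv_se=tstv_se,
        gc_eqm=gceq, gc_eqm_se=gceq_se,
    )


def signatures_by_bin(
    bin_frames: Sequence[tuple[str, pd.DataFrame]],
    at_sites: int,
    gc_sites: int,
    convention: str = "exclude_nonsense",
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy table of selection signatures, one row per (ordered) bin.

    ``bin_frames`` is a sequence of (label, annotated SNP frame) ordered
    young -> old or rare -> common.
    """
    rows = []
    for i, (label, df) in enumerate(bin_frames):
        sig = signature_for(
            df, at_sites, gc_sites, label=label, convention=convention,
            n_boot=n_boot, seed=seed + 10 * i,
        )
        rows.append(vars(sig))
    return pd.DataFrame(rows)
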
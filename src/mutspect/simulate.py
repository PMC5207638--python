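"""Synthetic clonal populations with a known mutation spectrum and selection.

The generator emulates what a set of clonally related strains looks like to
a population resequencing pipeline:

1. a reference genome is drawn at a requested GC content, with
   non-overlapping protein-coding intervals (uniform sense codons, ATG
   start, stop end, random strand) covering a requested coding fraction;
2. the strains are related by a random bifurcating genealogy with
   exponential (coalescent-like) waiting times; an optional closest-pair
   depth forces at least one very recently diverged strain pair, without
   which very young singletons would not exist;
3. mutations fall on branches as a Poisson process.  Each SNP event draws a
   strand-collapsed class from the spectrum and a position uniformly among
   genomic sites whose collapsed focal base matches the class source
   (triplet-context modifiers re-weight eligible sites); indel events fall
   uniformly, half insertions half deletions, with short geometric lengths;
4. age-dependent purifying selection: a nonsynonymous or nonsense SNP of
   true age a survives with probability 2^(-a/selection_halflife);
   coding indels decay with a separate (typically stronger) half-life;
   synonymous and noncoding events always survive.  Time units are
   arbitrary — only relative ages matter;
5. survivors are emitted as a multi-sample variant set with idealised
   qualities (MQ=60, GQ=99, QUAL=100, DP=50, half the reads supporting the
   alternate allele) so filter behaviour can be tested by deliberate
   fixture corruption rather than entangled with the simulation, together
   with a truth ledger mapping every emitted mutation to its branch, true
   age, and coding effect.

Second hits on an occupied position are re-dropped, so multi-allelic sites
are never generated, mirroring the exclusion of suspected >2-allele sites
from the analysis.  Strains are haploid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import VariantRecord
from .indels import left_normalize
from .spectrum import (
    CLASSES6,
    SENSE_CODONS,
    STOP_CODONS,
    EffectClassifier,
    collapse_context,
    complement,
    revcomp,
)


class SimulationError(RuntimeError):
    """The simulation cannot proceed (empty genealogy, no eligible sites...)."""


class PlacementError(SimulationError):
    """Coding intervals could not be placed at the requested fraction."""


#: GC fraction of the 61 sense codons at uniform codon usage
GC_SENSE: float = sum(
    c.count("G") + c.count("C") for c in SENSE_CODONS
) / (3 * len(SENSE_CODONS))

#: idealised quality metrics carried by every emitted record
IDEAL_QUAL = 100.0
IDEAL_MQ = 60.0
IDEAL_GQ = 99.0
IDEAL_DP = 50.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpectrum:
    """Strand-collapsed 6-class mutation spectrum, optionally with 32
    triplet-context modifiers.

    ``class_probs`` maps the classes C>T, C>A, C>G, T>C, T>A, T>G to
    probabilities summing to one.  ``context_modifiers`` maps collapsed
    triplets (5' base + focal pyrimidine + 3' base, e.g. ``"CCG"``) to
    positive multiplicative site weights.
    """

    class_probs: Mapping[str, float]
    context_modifiers: Mapping[str, float] | None = None

    def __post_init__(self):
        probs = dict(self.class_probs)
        if set(probs) != set(CLASSES6):
            raise ValueError(f"class_probs must have keys {CLASSES6}")
        if any(p < 0 for p in probs.values()):
            raise ValueError("class probabilities must be nonnegative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if self.context_modifiers is not None:
            for trip, w in self.context_modifiers.items():
                if len(trip) != 3 or trip[1] not in "CT":
                    raise ValueError(
                        f"context key {trip!r} is not a collapsed triplet"
                    )
                if w <= 0:
                    raise ValueError("context modifiers must be positive")
        object.__setattr__(self, "class_probs", probs)

    @property
    def probs_array(self) -> np.ndarray:
        return np.array([self.class_probs[k] for k in CLASSES6])

    @property
    def ts_fraction(self) -> float:
        """Probability that an event is a transition (C>T or T>C)."""
        return self.class_probs["C>T"] + self.class_probs["T>C"]

    @classmethod
    def uniform(cls) -> "MutationSpectrum":
        return cls({k: 1 / 6 for k in CLASSES6})

    @classmethod
    def ma_reference(
        cls,
        gc_content: float = 0.38,
        ts_tv: float = 1.0,
        gc_equilibrium: float = 32.0,
        conservative_mass: float = 0.2,
    ) -> "MutationSpectrum":
        """A spectrum whose emitted variants have the given transition:
        transversion event odds and whose per-site fluxes imply the given
        GC equilibrium percentage on a genome of ``gc_content``.

        Defaults reproduce the mutation-accumulation reference values for
        yeast (Ts/Tv = 1, GCeqm = 32%) on a 38% GC genome.
        ``conservative_mass`` is the total probability of the
        GC-conservative classes C>G and T>A, split equally.
        """
        g = gc_content
        e = gc_equilibrium / 100.0
        # v/u = e/(1-e); v = a/(1-g), u = b/g  =>  a/b = (e/(1-e)) * (1-g)/g
        r = (e / (1 - e)) * ((1 - g) / g)
        c = conservative_mass
        b = (1 - c) / (1 + r)  # GC->AT event mass (C>T + C>A)
        a = r * b              # AT->GC event mass (T>C + T>G)
        s = ts_tv / (1 + ts_tv)  # transition fraction of events
        p_ct = s * b / (a + b)
        p_tc = s * a / (a + b)
        return cls({
            "C>T": p_ct, "C>A": b - p_ct, "C>G": c / 2,
            "T>C": p_tc, "T>G": a - p_tc, "T>A": c / 2,
        })

    def to_dict(self) -> dict:
        return {
            "class_probs": dict(self.class_probs),
            "context_modifiers": (
                dict(self.context_modifiers)
                if self.context_modifiers is not None else None
            ),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MutationSpectrum":
        return cls(d["class_probs"], d.get("context_modifiers"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic population.

    ``mutations_per_kb_total_depth`` is the mean mutational input per kb of
    genome summed over all branches of the genealogy;
    ``terminal_branch_fraction`` is the fraction of that input falling on
    terminal branches (these mutations are the singletons);
    ``selection_halflife`` is the true-age scale (in the genealogy's
    arbitrary time units) at which a nonsynonymous mutation's survival
    probability halves (``inf`` disables selection);
    ``closest_pair_depth`` forces the most recent divergence to the given
    depth so that very young singletons exist.
    """

    n_strains: int = 20
    chromosome_lengths: tuple[int, ...] = (300_000, 200_000, 120_000)
    gc_content: float = 0.38
    coding_fraction: float = 0.70
    spectrum: MutationSpectrum = field(default_factory=MutationSpectrum.uniform)
    mutations_per_kb_total_depth: float = 10.0
    terminal_branch_fraction: float = 0.5
    closest_pair_depth: float | None = 0.02
    selection_halflife: float = 0.25
    indel_selection_halflife: float = 0.08
    indel_rate_relative: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 3:
            raise ValueError("n_strains must be >= 3")
        if any(length < 1000 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be >= 1000 bp")
        for name in ("gc_content", "coding_fraction", "terminal_branch_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutations_per_kb_total_depth < 0:
            raise ValueError("mutations_per_kb_total_depth must be >= 0")
        if self.selection_halflife <= 0 or self.indel_selection_halflife <= 0:
            raise ValueError("selection half-lives must be positive (or inf)")
        if self.indel_rate_relative < 0:
            raise ValueError("indel_rate_relative must be >= 0")
        if self.closest_pair_depth is not None and self.closest_pair_depth <= 0:
            raise ValueError("closest_pair_depth must be positive or None")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chromosome_lengths)))

    @property
    def strain_names(self) -> tuple[str, ...]:
        return tuple(f"strain{i:03d}" for i in range(self.n_strains))

    def to_dict(self) -> dict:
        return {
            "n_strains": self.n_strains,
            "chromosome_lengths": list(self.chromosome_lengths),
            "gc_content": self.gc_content,
            "coding_fraction": self.coding_fraction,
            "spectrum": self.spectrum.to_dict(),
            "mutations_per_kb_total_depth": self.mutations_per_kb_total_depth,
            "terminal_branch_fraction": self.terminal_branch_fraction,
            "closest_pair_depth": self.closest_pair_depth,
            "selection_halflife": self.selection_halflife,
            "indel_selection_halflife": self.indel_selection_halflife,
            "indel_rate_relative": self.indel_rate_relative,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["chromosome_lengths"] = tuple(d["chromosome_lengths"])
        d["spectrum"] = MutationSpectrum.from_dict(d["spectrum"])
        for key in ("selection_halflife", "indel_selection_halflife"):
            if isinstance(d.get(key), str):
                d[key] = float(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)
    return codes.tobytes().decode()


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Reference genome and coding annotation for one simulation.

    Returns (genome, annotation): ``genome`` maps chromosome name to an
    uppercase sequence at the requested GC content (noncoding composition is
    adjusted to compensate for the ~51% GC of uniform sense codons);
    ``annotation`` has 1-based inclusive columns chrom/start/end/strand, one
    row per coding interval, every interval a multiple of 3 bp starting ATG
    and ending with a stop codon on its strand.
    """
    rng = np.random.default_rng([config.seed, 0])
    stops = sorted(STOP_CODONS)
    genome: dict[str, str] = {}
    ann_rows = []
    for chrom, length in zip(config.chrom_names, config.chromosome_lengths):
        target = round(length * config.coding_fraction)
        gene_codons: list[int] = []
        total = 0
        while total + 30 <= target:
            n_cod = int(rng.integers(100, 501))
            n_cod = min(n_cod, max(10, (target - total) // 3))
            gene_codons.append(n_cod)
            total += 3 * n_cod
        realized = total / length
        if abs(realized - config.coding_fraction) > 0.02:
            raise PlacementError(
                f"cannot place coding intervals at fraction "
                f"{config.coding_fraction} on {chrom} ({length} bp); "
                f"realised {realized:.3f}"
            )
        noncoding_total = length - total
        n_gaps = len(gene_codons) + 1
        gaps = rng.multinomial(noncoding_total, np.full(n_gaps, 1.0 / n_gaps))
        coding_frac_real = total / length
        if coding_frac_real < 1.0:
            gc_nc = (config.gc_content - coding_frac_real * GC_SENSE) / (
                1.0 - coding_frac_real
            )
            gc_nc = float(np.clip(gc_nc, 0.02, 0.98))
        else:
            gc_nc = config.gc_content
        parts: list[str] = []
        pos = 0
        for gi, n_cod in enumerate(gene_codons):
            parts.append(_random_bases(rng, int(gaps[gi]), gc_nc))
            pos += int(gaps[gi])
            middle = "".join(
                SENSE_CODONS[i]
                for i in rng.integers(0, len(SENSE_CODONS), n_cod - 2)
            )
            mrna = "ATG" + middle + stops[rng.integers(0, 3)]
            strand = "+" if rng.random() < 0.5 else "-"
            seq = mrna if strand == "+" else revcomp(mrna)
            parts.append(seq)
            ann_rows.append(
                {"chrom": chrom, "start": pos + 1, "end": pos + 3 * n_cod,
                 "strand": strand}
            )
            pos += 3 * n_cod
        parts.append(_random_bases(rng, int(gaps[-1]), gc_nc))
        genome[chrom] = "".join(parts)
        assert len(genome[chrom]) == length
    annotation = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "strand"]
    )
    return genome, annotation


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    """One branch of the genealogy, from child node up to its parent.

    Depths are measured from the tips (time 0) toward the root.
    """

    node: int
    parent: int
    t_low: float
    t_high: float
    tips: tuple[int, ...]

    @property
    def length(self) -> float:
        return self.t_high - self.t_low

    @property
    def is_terminal(self) -> bool:
        return len(self.tips) == 1


def sample_genealogy(
    n_strains: int,
    rng: np.random.Generator,
    closest_pair_depth: float | None = None,
) -> list[Branch]:
    """A random bifurcating tree with exponential (coalescent) waiting times.

    With ``closest_pair_depth`` the first (most recent) coalescence is forced
    to that depth between a random pair, guaranteeing one very recently
    diverged strain pair.
    """
    if n_strains < 2:
        raise SimulationError("a genealogy needs at least two strains")
    active: dict[int, tuple[float, tuple[int, ...]]] = {
        i: (0.0, (i,)) for i in range(n_strains)
    }
    branches: list[Branch] = []
    t = 0.0
    next_node = n_strains
    k = n_strains
    while k > 1:
        rate = k * (k - 1) / 2.0
        if k == n_strains and closest_pair_depth is not None:
            t = closest_pair_depth
        else:
            t += rng.exponential(1.0 / rate)
        keys = sorted(active)
        i, j = rng.choice(len(keys), size=2, replace=False)
        a, b = keys[int(i)], keys[int(j)]
        tips: tuple[int, ...] = tuple(
            sorted(active[a][1] + active[b][1])
        )
        for child in (a, b):
            t_low, child_tips = active.pop(child)
            branches.append(
                Branch(node=child, parent=next_node, t_low=t_low, t_high=t,
                       tips=child_tips)
            )
        active[next_node] = (t, tips)
        next_node += 1
        k -= 1
    return branches


# ---------------------------------------------------------------------------
# mutation placement
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


class _SiteSampler:
    """Weighted sampling of genomic sites by collapsed source base."""

    def __init__(
        self,
        genome: Mapping[str, str],
        chrom_names: Sequence[str],
        spectrum: MutationSpectrum,
        rng: np.random.Generator,
    ):
        self._rng = rng
        self._chrom_names = list(chrom_names)
        seqs = [genome[c] for c in self._chrom_names]
        self._offsets = np.concatenate(
            [[0], np.cumsum([len(s) for s in seqs])]
        )
        codes = np.concatenate(
            [_BASE_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
             for s in seqs]
        )
        self._seq = "".join(seqs)
        # collapsed source: C for C/G sites, T for T/A sites
        source_c = (codes == 1) | (codes == 2)
        source_t = (codes == 0) | (codes == 3)
        if spectrum.context_modifiers is not None:
            # exclude the two edge sites of each chromosome (no full triplet)
            edge = np.zeros(len(codes), dtype=bool)
            for lo, hi in zip(self._offsets[:-1], self._offsets[1:]):
                edge[lo] = True
                edge[hi - 1] = True
            source_c &= ~edge
            source_t &= ~edge
        self._idx: dict[str, np.ndarray] = {
            "C": np.flatnonzero(source_c),
            "T": np.flatnonzero(source_t),
        }
        self._cum: dict[str, np.ndarray | None] = {"C": None, "T": None}
        if spectrum.context_modifiers is not None:
            mods = spectrum.context_modifiers
            for source in "CT":
                idx = self._idx[source]
                weights = np.array([
                    mods.get(collapse_context(self._seq[i - 1:i + 2]), 1.0)
                    for i in idx
                ])
                self._cum[source] = np.cumsum(weights)

    def sample(self, source: str, k: int) -> np.ndarray:
        """``k`` global site indices for a collapsed source base."""
        idx = self._idx[source]
        if len(idx) == 0:
            raise SimulationError(
                f"no eligible sites for source base {source}"
            )
        cum = self._cum[source]
        if cum is None:
            return idx[self._rng.integers(0, len(idx), size=k)]
        r = self._rng.random(k) * cum[-1]
        return idx[np.searchsorted(cum, r, side="right")]

    def locate(self, gidx: int) -> tuple[str, int]:
        """(chromosome, 1-based position) of a global site index."""
        ci = int(np.searchsorted(self._offsets, gidx, side="right")) - 1
        return self._chrom_names[ci], int(gidx - self._offsets[ci]) + 1

    def base(self, gidx: int) -> str:
        return self._seq[gidx]


def _survival(age: float, halflife: float) -> float:
    if math.isinf(halflife):
        return 1.0
    return 2.0 ** (-age / halflife)


TRUTH_COLUMNS = ("chrom", "pos", "ref", "alt", "carriers", "branch_id",
                 "true_age", "effect")


def simulate_population(
    config: SimulationConfig,
    genome: Mapping[str, str],
    annotation: pd.DataFrame,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Simulate the population and return (variant records, truth ledger).

    The ledger has one row per *emitted* (post-selection) mutation with
    columns chrom, pos, ref, alt, carriers (comma-joined strain names),
    branch_id, true_age, effect; effects are synonymous / nonsynonymous /
    nonsense / noncoding / indel_coding / indel_noncoding.
    """
    rng = np.random.default_rng([config.seed, 1])
    branches = sample_genealogy(
        config.n_strains, rng, config.closest_pair_depth
    )
    if not branches:
        raise SimulationError("empty genealogy")
    lengths = np.array([b.length for b in branches])
    terminal = np.array([b.is_terminal for b in branches])
    weights = lengths.copy()
    term_len = lengths[terminal].sum()
    int_len = lengths[~terminal].sum()
    f = config.terminal_branch_fraction
    if f == 0.0:
        weights[terminal] = 0.0
    elif f == 1.0:
        weights[~terminal] = 0.0
    elif term_len > 0 and int_len > 0:
        weights[terminal] *= f * int_len / ((1.0 - f) * term_len)
    if weights.sum() == 0:
        raise SimulationError("genealogy carries no mutational opportunity")
    branch_p = weights / weights.sum()

    genome_kb = sum(len(genome[c]) for c in config.chrom_names) / 1000.0
    mean_snv = config.mutations_per_kb_total_depth * genome_kb
    n_snv = int(rng.poisson(mean_snv)) if mean_snv > 0 else 0
    mean_indel = mean_snv * config.indel_rate_relative
    n_indel = int(rng.poisson(mean_indel)) if mean_indel > 0 else 0

    classifier = EffectClassifier(genome, annotation)
    strain_names = config.strain_names
    t_low = np.array([b.t_low for b in branches])
    t_high = np.array([b.t_high for b in branches])

    occupied: set[tuple[str, int]] = set()
    mutations: list[dict] = []

    if n_snv:
        sampler = _SiteSampler(genome, config.chrom_names, config.spectrum, rng)
        class_ix = rng.choice(6, size=n_snv, p=config.spectrum.probs_array)
        branch_ix = rng.choice(len(branches), size=n_snv, p=branch_p)
        ages = t_low[branch_ix] + rng.random(n_snv) * (
            t_high[branch_ix] - t_low[branch_ix]
        )
        for m in range(n_snv):
            cls = CLASSES6[class_ix[m]]
            source, target = cls[0], cls[2]
            for _ in range(1000):
                gidx = int(sampler.sample(source, 1)[0])
                chrom, pos = sampler.locate(gidx)
                if (chrom, pos) not in occupied:
                    break
            else:
                raise SimulationError(
                    f"could not find a free {source}-source site"
                )
            ref = sampler.base(gidx)
            alt = target if ref == source else complement(target)
            effect = classifier.classify(chrom, pos, ref, alt)
            age = float(ages[m])
            if effect in ("nonsynonymous", "nonsense"):
                if rng.random() >= _survival(age, config.selection_halflife):
                    continue
            occupied.add((chrom, pos))
            branch = branches[branch_ix[m]]
            mutations.append({
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "tips": branch.tips, "branch_id": branch.node,
                "true_age": age, "effect": effect,
            })

    if n_indel:
        chrom_lens = np.array(
            [len(genome[c]) for c in config.chrom_names], dtype=float
        )
        chrom_p = chrom_lens / chrom_lens.sum()
        branch_ix = rng.choice(len(branches), size=n_indel, p=branch_p)
        ages = t_low[branch_ix] + rng.random(n_indel) * (
            t_high[branch_ix] - t_low[branch_ix]
        )
        for m in range(n_indel):
            for _ in range(1000):
                ci = int(rng.choice(len(chrom_lens), p=chrom_p))
                chrom = config.chrom_names[ci]
                seq = genome[chrom]
                d = min(int(rng.geometric(0.5)), 6)
                is_insertion = rng.random() < 0.5
                pos = int(rng.integers(1, len(seq) - d))
                if is_insertion:
                    ins = "".join(
                        "ACGT"[i] for i in rng.integers(0, 4, d)
                    )
                    ref = seq[pos - 1]
                    alt = ref + ins
                else:
                    ref = seq[pos - 1:pos + d]
                    alt = seq[pos - 1]
                pos, ref, alt = left_normalize(seq, pos, ref, alt)
                if (chrom, pos) not in occupied:
                    break
            else:
                raise SimulationError("could not place an indel")
            anchor = pos + 1
            coding = classifier.coding_interval(chrom, anchor) is not None
            effect = "indel_coding" if coding else "indel_noncoding"
            age = float(ages[m])
            if coding:
                if rng.random() >= _survival(
                    age, config.indel_selection_halflife
                ):
                    continue
            occupied.add((chrom, pos))
            branch = branches[branch_ix[m]]
            mutations.append({
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "tips": branch.tips, "branch_id": branch.node,
                "true_age": age, "effect": effect,
            })

    chrom_order = {c: i for i, c in enumerate(config.chrom_names)}
    mutations.sort(key=lambda m: (chrom_order[m["chrom"]], m["pos"]))

    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    n = config.n_strains
    for m in mutations:
        gt = np.zeros(n, dtype=bool)
        gt[list(m["tips"])] = True
        records.append(VariantRecord(
            chrom=m["chrom"], pos=m["pos"], ref=m["ref"], alt=m["alt"],
            qual=IDEAL_QUAL, mq=IDEAL_MQ, strains=strain_names,
            gt=gt,
            gq=np.full(n, IDEAL_GQ),
            dp=np.full(n, IDEAL_DP),
            alt_reads=np.where(gt, IDEAL_DP / 2, 0.0),
        ))
        truth_rows.append({
            "chrom": m["chrom"], "pos": m["pos"], "ref": m["ref"],
            "alt": m["alt"],
            "carriers": ",".join(strain_names[t] for t in m["tips"]),
            "branch_id": m["branch_id"], "true_age": m["true_age"],
            "effect": m["effect"],
        })
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return records, truth
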
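"""End-to-end orchestration: simulate -> filter -> age -> spectrum -> indels.

`run_pipeline` drives one reproducible run from a :class:`RunConfig`,
writing every stage's table with the seed in its header; `analyze_cohort`
and the small helpers around it expose the same flow in memory for
programmatic use (parameter-recovery studies, acceptance checks).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import aging, indels as indel_mod, io, spectrum as spec
from .filtering import FilterConfig, apply_filters, split_snps_indels
from .simulate import SimulationConfig, generate_reference, simulate_population

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    The simulation seed is the single source of randomness; it is recorded
    in the header of every output file.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    n_age_bins: int = 10
    young_edges: tuple[float, ...] | None = None
    pooled_ages: bool = False
    #: age against analysed (mask-subtracted) chromosome length instead of
    #: full length
    effective_length: bool = False
    nonsense_convention: str = "exclude_nonsense"
    n_boot: int = 500
    #: lower carrier-count edges of the population-frequency classes
    frequency_edges: tuple[int, ...] = (1, 2, 4, 8)
    indel_age_edges: tuple[float, ...] | None = None
    indel_age_bins: int = 4

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def to_dict(self) -> dict:
        d = {
            "simulation": self.simulation.to_dict(),
            "filters": dataclasses.asdict(self.filters),
        }
        for f in dataclasses.fields(self):
            if f.name in ("simulation", "filters"):
                continue
            value = getattr(self, f.name)
            d[f.name] = list(value) if isinstance(value, tuple) else value
        d["filters"]["mask_intervals"] = [
            list(iv) for iv in self.filters.mask_intervals
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        kwargs: dict = {}
        kwargs["simulation"] = SimulationConfig.from_dict(d.pop("simulation"))
        filt = dict(d.pop("filters", {}))
        filt["mask_intervals"] = tuple(
            tuple(iv) for iv in filt.get("mask_intervals", ())
        )
        kwargs["filters"] = FilterConfig(**filt)
        for f in dataclasses.fields(cls):
            if f.name in kwargs or f.name not in d:
                continue
            value = d[f.name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Cohort:
    """In-memory result of the simulate/filter/age stages of one run."""

    config: RunConfig
    genome: dict[str, str]
    annotation: pd.DataFrame
    truth: pd.DataFrame
    records: list
    kept: list
    tally: dict[str, int]
    snps: list
    indel_records: list
    discarded: list
    classifier: spec.EffectClassifier
    chromosome_lengths: dict[str, int]
    singletons: list
    at_sites: int
    gc_sites: int


def _aging_lengths(config: RunConfig, genome: Mapping[str, str]) -> dict[str, int]:
    lengths = {c: len(s) for c, s in genome.items()}
    if config.effective_length:
        masked = {c: 0 for c in lengths}
        for chrom, start, end in config.filters.mask_intervals:
            if chrom in masked:
                masked[chrom] += min(end, lengths[chrom]) - start
        lengths = {c: lengths[c] - masked[c] for c in lengths}
    return lengths


def analyze_cohort(config: RunConfig) -> Cohort:
    """Simulate one population and run it through filtering and aging."""
    genome, annotation = generate_reference(config.simulation)
    records, truth = simulate_population(config.simulation, genome, annotation)
    kept, tally = apply_filters(records, config.filters)
    n_rejected = sum(tally.values())
    logger.info(
        "filter: %d in = %d kept + %d rejected", len(records), len(kept),
        n_rejected,
    )
    assert len(records) == len(kept) + n_rejected
    snps, indel_records, discarded = split_snps_indels(kept)
    lengths = _aging_lengths(config, genome)
    singles = aging.identify_singletons(snps)
    singles = aging.assign_ages(singles, lengths, pooled=config.pooled_ages)
    mask = config.filters.mask_intervals
    at_sites, gc_sites = spec.at_gc_site_counts(genome, mask)
    return Cohort(
        config=config, genome=genome, annotation=annotation, truth=truth,
        records=records, kept=kept, tally=tally, snps=snps,
        indel_records=indel_records, discarded=discarded,
        classifier=spec.EffectClassifier(genome, annotation),
        chromosome_lengths=lengths, singletons=singles,
        at_sites=at_sites, gc_sites=gc_sites,
    )


def _annotated_frame(cohort: Cohort, singletons: Sequence) -> pd.DataFrame:
    df = aging.singletons_to_frame(singletons)
    return spec.annotate_snp_frame(
        df, genome=cohort.genome, classifier=cohort.classifier
    )


def age_bin_frames(
    cohort: Cohort,
    n_bins: int | None = None,
    young_edges: Sequence[float] | None = None,
) -> tuple[list[aging.AgeBin], list[tuple[str, pd.DataFrame]]]:
    """Age bins of the cohort's SNP singletons plus annotated member frames,
    ordered young -> old."""
    cfg = cohort.config
    bins = aging.bin_by_age(
        cohort.singletons,
        cfg.n_age_bins if n_bins is None else n_bins,
        young_edges=cfg.young_edges if young_edges is None else young_edges,
    )
    frames = [
        (b.label, _annotated_frame(cohort, b.members)) for b in bins
    ]
    return bins, frames


def frequency_class_frames(
    cohort: Cohort,
) -> list[tuple[str, pd.DataFrame]]:
    """Annotated SNP frames per population-frequency (carrier-count) class,
    rare -> common."""
    cfg = cohort.config
    n = cfg.simulation.n_strains
    edges = [*cfg.frequency_edges, n + 1]
    frames = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [r for r in cohort.snps if lo <= r.n_carriers < hi]
        label = f"k={lo}" if hi == lo + 1 else f"k={lo}-{hi - 1}"
        df = pd.DataFrame(
            [{"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt}
             for r in members],
            columns=["chrom", "pos", "ref", "alt"],
        )
        frames.append((label, spec.annotate_snp_frame(
            df, genome=cohort.genome, classifier=cohort.classifier
        )))
    return frames


def youngest_bin_signature(
    config: RunConfig,
    n_boot: int | None = None,
) -> spec.SelectionSignature:
    """Selection signature of the youngest age bin of one simulated cohort."""
    cohort = analyze_cohort(config)
    _, frames = age_bin_frames(cohort)
    label, df = frames[0]
    return spec.signature_for(
        df, cohort.at_sites, cohort.gc_sites, label=label,
        convention=config.nonsense_convention,
        n_boot=config.n_boot if n_boot is None else n_boot,
        seed=config.seed,
    )


def aged_indels(cohort: Cohort) -> list:
    """The cohort's singleton indels, flank-annotated and density-aged."""
    recs, _ = indel_mod.build_indel_records(
        cohort.indel_records, cohort.genome
    )
    return indel_mod.age_indels(
        recs, cohort.chromosome_lengths, pooled=cohort.config.pooled_ages
    )


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Run all stages and write every figure-level table under ``outdir``.

    Returns the result tables as a dict of DataFrames.  Re-running with an
    identical config reproduces every output byte for byte.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    results: dict = {}

    cohort = analyze_cohort(config)
    contigs = {c: len(s) for c, s in cohort.genome.items()}

    io.write_fasta(cohort.genome, out / "reference.fa")
    io.write_annotation_bed(cohort.annotation, out / "genes.bed")
    io.write_annotation_gff3(cohort.annotation, out / "genes.gff3")
    strains = cohort.config.simulation.strain_names
    io.write_vcf(cohort.records, strains, contigs, out / "variants.vcf",
                 seed=seed)
    io.write_tsv(cohort.truth, out / "truth.tsv", seed=seed)
    io.write_vcf(cohort.kept, strains, contigs, out / "filtered.vcf",
                 seed=seed)

    tally = pd.DataFrame(
        [{"rule": k, "rejected": v} for k, v in cohort.tally.items()]
    )
    io.write_tsv(tally, out / "rejection_tally.tsv", seed=seed)
    logger.info(
        "conservation: %d in = %d kept + %d rejected",
        len(cohort.records), len(cohort.kept), int(tally["rejected"].sum()),
    )
    results["tally"] = tally

    n_strains = config.simulation.n_strains
    freq = aging.population_frequency(cohort.snps, n_strains)
    sfs = aging.site_frequency_spectrum(cohort.snps, n_strains)
    io.write_tsv(freq, out / "frequency.tsv", seed=seed)
    io.write_tsv(sfs.reset_index(), out / "sfs.tsv", seed=seed)
    results["sfs"] = sfs

    bins, frames = age_bin_frames(cohort)
    singles_table = aging.singletons_to_frame(cohort.singletons, bins)
    io.write_tsv(singles_table, out / "singletons.tsv", seed=seed)
    logger.info(
        "aging: %d SNPs -> %d singletons in %d bins",
        len(cohort.snps), len(cohort.singletons), len(bins),
    )

    sig_age = spec.signatures_by_bin(
        frames, cohort.at_sites, cohort.gc_sites,
        convention=config.nonsense_convention,
        n_boot=config.n_boot, seed=seed,
    )
    io.write_tsv(sig_age, out / "signatures_by_age.tsv", seed=seed)
    results["signatures_by_age"] = sig_age

    freq_frames = frequency_class_frames(cohort)
    sig_freq = spec.signatures_by_bin(
        freq_frames, cohort.at_sites, cohort.gc_sites,
        convention=config.nonsense_convention,
        n_boot=config.n_boot, seed=seed + 1,
    )
    io.write_tsv(sig_freq, out / "signatures_by_frequency.tsv", seed=seed)
    results["signatures_by_frequency"] = sig_freq

    mask = config.filters.mask_intervals
    if frames and len(frames[0][1]) and len(frames[-1][1]):
        young_df, old_df = frames[0][1], frames[-1][1]
        rates_young = spec.relative_rates_6class(
            young_df, cohort.genome, mask, n_boot=config.n_boot, seed=seed
        )
        rates_old = spec.relative_rates_6class(
            old_df, cohort.genome, mask, n_boot=config.n_boot, seed=seed + 1
        )
        io.write_tsv(rates_young.reset_index(), out / "rates6_young.tsv",
                     seed=seed)
        io.write_tsv(rates_old.reset_index(), out / "rates6_old.tsv",
                     seed=seed)
        comparison = spec.compare_rates(rates_young, rates_old)
        io.write_tsv(comparison.reset_index(), out / "rates6_young_vs_old.tsv",
                     seed=seed)
        results["rates6_young"] = rates_young
        results["rates6_old"] = rates_old
        results["rates6_comparison"] = comparison

    all_singles = _annotated_frame(cohort, cohort.singletons)
    if len(all_singles):
        rates32 = spec.context_rates_32(
            all_singles, cohort.genome, mask, n_boot=config.n_boot, seed=seed
        )
        io.write_tsv(rates32.reset_index(), out / "rates32.tsv", seed=seed)
        results["rates32"] = rates32

    ind = aged_indels(cohort)
    io.write_tsv(indel_mod.indels_to_frame(ind), out / "indel_singletons.tsv",
                 seed=seed)
    if ind:
        flank = indel_mod.flank_base_composition(ind)
        strs = indel_mod.str_adjacency(ind)
        io.write_tsv(flank.reset_index(), out / "indel_flank_composition.tsv",
                     seed=seed)
        io.write_tsv(strs.reset_index(), out / "indel_str.tsv", seed=seed)
        coding = indel_mod.coding_fraction_by_age(
            ind, cohort.classifier,
            age_edges=config.indel_age_edges, n_bins=config.indel_age_bins,
        )
        io.write_tsv(coding, out / "indel_coding_by_age.tsv", seed=seed)
        results["indel_flank_composition"] = flank
        results["indel_str"] = strs
        results["indel_coding_by_age"] = coding

    summary = pd.DataFrame([
        {"stage": "simulated", "count": len(cohort.records)},
        {"stage": "filtered_kept", "count": len(cohort.kept)},
        {"stage": "filtered_rejected", "count": int(tally["rejected"].sum())},
        {"stage": "snps", "count": len(cohort.snps)},
        {"stage": "indels", "count": len(cohort.indel_records)},
        {"stage": "discarded_multiallelic", "count": len(cohort.discarded)},
        {"stage": "snp_singletons", "count": len(cohort.singletons)},
        {"stage": "indel_singletons", "count": len(ind)},
    ])
    io.write_tsv(summary, out / "summary.tsv", seed=seed)
    results["summary"] = summary
    results["cohort"] = cohort
    return results


def _reseeded(config: RunConfig, seed: int) -> RunConfig:
    """A copy of ``config`` with the simulation seed replaced."""
    sim = dataclasses.replace(config.simulation, seed=seed)
    return dataclasses.replace(config, simulation=sim)


def recovery_study(
    base: RunConfig,
    seeds: Sequence[int],
    n_boot: int | None = None,
) -> pd.DataFrame:
    """Youngest-bin signatures across replicate seeds (parameter recovery)."""
    rows = []
    for s in seeds:
        sig = youngest_bin_signature(_reseeded(base, s), n_boot=n_boot)
        row = vars(sig)
        row["seed"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def no_selection(config: RunConfig) -> RunConfig:
    """A copy of ``config`` with purifying selection disabled."""
    sim = dataclasses.replace(
        config.simulation,
        selection_halflife=math.inf, indel_selection_halflife=math.inf,
    )
    return dataclasses.replace(config, simulation=sim)
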
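"""End-to-end orchestration: ingest or simulate, then run every analysis
stage and write a reproducible report bundle.

Stages run in dependency order (inputs → diversity → RoH → load → phylogeny
→ significance tests → summary); a stage failure aborts with the stage
name. With a fixed seed the whole report is deterministic; no timestamps
enter any output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, io_formats, load, phylo, roh, scenarios, stats
from .model import GenotypeMatrix, SampleTable
from .roh import RohParameters

log = logging.getLogger(__name__)

#: mutation rate used to convert heterozygosity to effective size when
#: analysing real data (per site per generation, mid-range teleost estimate)
DEFAULT_MU = 3.0e-9


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "vcf-bundle"
    scenario: str = "paper-like"  # synthetic mode: "paper-like" | "two-deme"
    seed: int = 1
    out_dir: str = "driftprint_out"
    # input paths for vcf-bundle mode
    vcf: str | None = None
    samples: str | None = None
    annotation: str | None = None
    reference: str | None = None
    conservation: str | None = None
    outgroup: str | None = None
    outgroup_label: str = "outgroup"
    # analysis parameters (replication preset values)
    mu: float = DEFAULT_MU
    ne_convention: str = diversity.PAPER_CALIBRATED
    gerp_threshold: float = load.GERP_DELETERIOUS_THRESHOLD
    weighting: str = "presence"
    metric: str = phylo.ALLELE_SHARING
    n_bootstrap: int = 500
    roh_params: dict = field(default_factory=dict)

    def roh_parameters(self) -> RohParameters:
        return RohParameters(**self.roh_params)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def replication_preset(**overrides) -> PipelineConfig:
    """Pin every replication-relevant parameter in one place: site filters
    geno 0.01 / maf 0.05, window-het 0, 0.5 Mb length floor, conservation
    threshold > 4, μ = 3e-9, 500 bootstrap pseudoreplicates, and the
    paper-calibrated Ne convention."""
    cfg = PipelineConfig(
        mu=3.0e-9,
        ne_convention=diversity.PAPER_CALIBRATED,
        gerp_threshold=4.0,
        n_bootstrap=500,
        roh_params={"geno": 0.01, "maf": 0.05, "window_het": 0, "min_length": 500_000},
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class ReportBundle:
    out_dir: str
    heterozygosity: pd.DataFrame
    het_summary: pd.DataFrame
    roh_segments: pd.DataFrame
    roh_summary: pd.DataFrame
    roh_pop_summary: pd.DataFrame
    load_profiles: pd.DataFrame | None
    load_summary: pd.DataFrame | None
    z_tests: pd.DataFrame
    correlation: stats.CorrelationResult | None
    summary_table: pd.DataFrame
    population_order: list[str]
    tree_path: str | None
    skipped: list[str]


# ---------------------------------------------------------------------------
# input validation

def validate_inputs(matrix: GenotypeMatrix, samples: SampleTable,
                    annotation=None, reference=None) -> list[dict]:
    """Machine-readable diagnostics; never mutates inputs."""
    findings: list[dict] = []
    table_samples = set(samples.samples)
    for s in matrix.samples:
        if s not in table_samples:
            findings.append({"kind": "sample_mismatch",
                             "detail": f"VCF sample {s!r} absent from sample table"})
    for s in samples.non_outgroup_samples():
        if s not in matrix.samples:
            findings.append({"kind": "sample_mismatch",
                             "detail": f"sample table entry {s!r} absent from VCF"})
    if not matrix.is_sorted():
        findings.append({"kind": "unsorted", "detail": "VCF sites not sorted by (chrom, pos)"})
    if (matrix.sites["pos"] < 1).any():
        findings.append({"kind": "coordinate", "detail": "non-positive VCF position"})
    bad = matrix.sites["ref"] == matrix.sites["alt"]
    if bad.any():
        findings.append({"kind": "alleles", "detail": "ref == alt at some site"})
    if annotation is not None:
        for t in annotation.transcripts:
            if (t.coding_length() - t.frame) % 3 != 0:
                findings.append({"kind": "frame",
                                 "detail": f"transcript {t.transcript_id} length not divisible by 3"})
            if reference is not None and t.chrom not in reference:
                findings.append({"kind": "reference",
                                 "detail": f"transcript {t.transcript_id} on unknown chrom {t.chrom}"})
    return findings


# ---------------------------------------------------------------------------
# pipeline

def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skipped: list[str] = []

    # ---- inputs ----------------------------------------------------------
    if config.mode == "synthetic":
        if config.scenario == "two-deme":
            cohort = scenarios.two_deme_bottleneck(config.seed)
        elif config.scenario == "paper-like":
            cohort = scenarios.paper_like_cohort(config.seed)
        else:
            raise ValueError(f"unknown scenario {config.scenario!r}")
        inputs = out / "inputs"
        from .synthetic import emit_bundle

        emit_bundle(cohort, inputs)
        matrix = cohort.matrix
        samples = cohort.samples
        annotation = cohort.annotation
        reference = cohort.reference
        conservation = io_formats.read_conservation(inputs / "conservation.bed")
        outgroup = io_formats.read_outgroup_alleles(inputs / "outgroup_alleles.tsv")
        # the generator's mutation rate is the right Ne-conversion rate here
        mu = 3.0e-7 if config.mu == DEFAULT_MU else config.mu
    elif config.mode == "vcf-bundle":
        if config.vcf is None or config.samples is None:
            raise ValueError("vcf-bundle mode requires vcf and samples paths")
        samples = io_formats.read_sample_table(config.samples)
        matrix = io_formats.read_vcf(config.vcf)
        if "callable_sites" in samples.table.columns:
            lut = dict(zip(samples.table["sample"], samples.table["callable_sites"]))
            if all(s in lut and pd.notna(lut[s]) for s in matrix.samples):
                matrix.callable_sites = np.asarray(
                    [lut[s] for s in matrix.samples], dtype=np.int64)
                matrix.callable_fallback = False
        annotation = io_formats.read_annotation(config.annotation) if config.annotation else None
        reference = io_formats.read_fasta(config.reference) if config.reference else None
        conservation = (io_formats.read_conservation(config.conservation)
                        if config.conservation else None)
        outgroup = (io_formats.read_outgroup_alleles(config.outgroup)
                    if config.outgroup else None)
        mu = config.mu
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    findings = validate_inputs(matrix, samples, annotation, reference)
    hard = [f for f in findings if f["kind"] == "sample_mismatch"]
    if hard:
        raise ValueError(f"inconsistent sample sets between inputs: {hard}")

    params = config.roh_parameters()

    # ---- diversity -------------------------------------------------------
    het = _stage("diversity")(diversity.heterozygosity_table)(matrix, samples)
    het["Ne"] = [diversity.estimate_ne(h, mu, config.ne_convention).Ne for h in het["H"]]

    # ---- RoH -------------------------------------------------------------
    @_stage("roh")
    def _roh():
        filt = roh.filter_sites(matrix, params, samples)
        segs = roh.scan_all_samples(filt, samples, params)
        return segs, roh.summarize_roh(segs, samples)

    segments, roh_summary = _roh()

    # ---- mutational load -------------------------------------------------
    profiles = None
    if annotation is not None and reference is not None:
        @_stage("load")
        def _load():
            counts = load.count_sites(annotation, reference)
            effects = load.classify_sites(matrix.sites, annotation, reference)
            scores = (conservation.scores_for_sites(matrix.sites)
                      if conservation is not None else None)
            derived = (load.polarize_sites(matrix.sites, outgroup)
                       if outgroup is not None else None)
            return load.load_profiles(
                matrix, effects, counts, samples, conservation_scores=scores,
                derived=derived, weighting=config.weighting,
                gerp_threshold=config.gerp_threshold,
            )

        profiles = _load()
        if conservation is None:
            skipped.append("deleterious category (no conservation track)")
    else:
        skipped.append("mutational load (no annotation/reference)")

    # ---- phylogeny -------------------------------------------------------
    tree_path = None
    population_order = samples.populations()

    @_stage("phylogeny")
    def _phylo():
        extra = None
        if outgroup is not None:
            extra = {config.outgroup_label: phylo.outgroup_genotypes(matrix.sites, outgroup)}
        labels, d = phylo.distance_matrix(matrix, metric=config.metric, extra_rows=extra)
        pops, pd_mat = phylo.population_distance_matrix(
            labels, d, samples,
            outgroup_label=config.outgroup_label if extra else None)
        sample_tree = phylo.bootstrap_supports(
            matrix, n_reps=config.n_bootstrap, seed=config.seed,
            metric=config.metric, extra_rows=extra)
        pop_tree = phylo.nj_tree(pops, pd_mat)
        if extra:
            sample_tree = phylo.root_tree(sample_tree, config.outgroup_label)
            pop_tree = phylo.root_tree(pop_tree, config.outgroup_label)
        return labels, d, pops, pd_mat, sample_tree, pop_tree

    if matrix.n_samples + (1 if outgroup is not None else 0) >= 3 and matrix.n_sites > 0:
        labels, dmat, pops, pop_d, sample_tree, pop_tree = _phylo()
        io_formats.write_newick(sample_tree, out / "tree_samples.nwk")
        io_formats.write_newick(pop_tree, out / "tree_populations.nwk")
        tree_path = str(out / "tree_samples.nwk")
        pd.DataFrame(dmat, index=labels, columns=labels).to_csv(
            out / "distances_samples.tsv", sep="\t")
        pd.DataFrame(pop_d, index=pops, columns=pops).to_csv(
            out / "distances_populations.tsv", sep="\t")
        population_order = _phylogeny_order(pop_tree, samples)
    else:
        skipped.append("phylogeny (fewer than 3 units)")

    # ---- summaries and tests --------------------------------------------
    het_summary = diversity.population_summary(het, "H", order=population_order)
    roh_count_summary = diversity.population_summary(
        roh_summary.rename(columns={"n_segments": "value"}), "value", order=population_order)
    roh_len_summary = diversity.population_summary(
        roh_summary.rename(columns={"total_length": "value"}), "value", order=population_order)
    roh_pop_summary = roh_count_summary.merge(
        roh_len_summary, on=["population", "n"], suffixes=("_count", "_length"))

    z_rows = []
    landlocked = samples.landlocked_populations()
    for ll in landlocked:
        for other in population_order:
            if other == ll or other not in set(het["population"]):
                continue
            for label, frame, col in (
                ("heterozygosity", het, "H"),
                ("roh_count", roh_summary, "n_segments"),
                ("roh_total_length", roh_summary, "total_length"),
            ):
                a = frame.loc[frame["population"] == ll, col]
                b = frame.loc[frame["population"] == other, col]
                if len(a) >= 2 and len(b) >= 2:
                    r = stats.z_test(a, b)
                    z_rows.append({"comparison": label, "group_a": ll, "group_b": other,
                                   "n_a": r.n_a, "n_b": r.n_b, "mean_a": r.mean_a,
                                   "mean_b": r.mean_b, "z": r.z, "p": r.p})
            if profiles is not None:
                for label, col in (("dnds", "dnds"),
                                   ("nonsynonymous_hom", "nonsynonymous_hom"),
                                   ("LoF_hom", "LoF_hom")):
                    if col not in profiles.columns:
                        continue
                    a = profiles.loc[profiles["population"] == ll, col].dropna()
                    b = profiles.loc[profiles["population"] == other, col].dropna()
                    if len(a) >= 2 and len(b) >= 2:
                        r = stats.z_test(a, b)
                        z_rows.append({"comparison": label, "group_a": ll, "group_b": other,
                                       "n_a": r.n_a, "n_b": r.n_b, "mean_a": r.mean_a,
                                       "mean_b": r.mean_b, "z": r.z, "p": r.p})
    z_tests = pd.DataFrame(z_rows)

    correlation = None
    if profiles is not None and len(profiles) >= 3:
        sub = het.merge(profiles[["sample", "dnds"]], on="sample").dropna(subset=["dnds"])
        if len(sub) >= 3 and sub["Ne"].std() > 0 and sub["dnds"].std() > 0:
            correlation = stats.pearson_with_p(sub["Ne"], sub["dnds"])

    load_summary = None
    if profiles is not None:
        parts = [diversity.population_summary(profiles, "dnds", order=population_order)
                 .rename(columns={"mean": "dnds_mean", "sem": "dnds_sem"})]
        for cat in ("nonsynonymous", "deleterious", "LoF"):
            col = f"{cat}_hom_fraction"
            if col in profiles.columns:
                p2 = diversity.population_summary(profiles, col, order=population_order)
                parts.append(p2.rename(columns={"mean": f"{col}_mean", "sem": f"{col}_sem"})
                             .drop(columns=["n"]))
        load_summary = parts[0]
        for p2 in parts[1:]:
            load_summary = load_summary.merge(p2, on="population")

    # ---- summary table ---------------------------------------------------
    summary = het_summary.rename(columns={"mean": "H_mean", "sem": "H_sem"})
    summary = summary.merge(
        roh_pop_summary.rename(columns={"mean_count": "roh_count_mean",
                                        "sem_count": "roh_count_sem",
                                        "mean_length": "roh_length_mean",
                                        "sem_length": "roh_length_sem"}),
        on=["population", "n"], how="left")
    if load_summary is not None:
        summary = summary.merge(load_summary.drop(columns=["n"]), on="population", how="left")

    # ---- write -----------------------------------------------------------
    het.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
    het_summary.to_csv(out / "het_population_summary.tsv", sep="\t", index=False)
    if not segments.empty:
        bed = segments.copy()
        bed["start0"] = bed["start"] - 1
        bed[["chrom", "start0", "end", "sample", "length", "n_snvs"]].to_csv(
            out / "roh_segments.bed", sep="\t", header=False, index=False)
    else:
        (out / "roh_segments.bed").write_text("")
    roh_summary.to_csv(out / "roh_summary.tsv", sep="\t", index=False)
    roh_pop_summary.to_csv(out / "roh_population_summary.tsv", sep="\t", index=False)
    if profiles is not None:
        profiles.to_csv(out / "load_profiles.tsv", sep="\t", index=False)
        load_summary.to_csv(out / "load_population_summary.tsv", sep="\t", index=False)
    z_tests.to_csv(out / "z_tests.tsv", sep="\t", index=False)
    if correlation is not None:
        pd.DataFrame([{"n": correlation.n, "r": correlation.r, "p": correlation.p,
                       "slope": correlation.slope, "intercept": correlation.intercept}]
                     ).to_csv(out / "correlation.tsv", sep="\t", index=False)
    summary.to_csv(out / "summary_table.tsv", sep="\t", index=False)

    run_log = {
        "seed": config.seed,
        "mode": config.mode,
        "parameters": asdict(config),
        "n_samples": matrix.n_samples,
        "n_sites": matrix.n_sites,
        "dropped_records": matrix.dropped,
        "callable_fallback": matrix.callable_fallback,
        "population_order": population_order,
        "skipped": skipped,
        "validation_findings": findings,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))

    return ReportBundle(
        out_dir=str(out), heterozygosity=het, het_summary=het_summary,
        roh_segments=segments, roh_summary=roh_summary,
        roh_pop_summary=roh_pop_summary, load_profiles=profiles,
        load_summary=load_summary, z_tests=z_tests, correlation=correlation,
        summary_table=summary, population_order=population_order,
        tree_path=tree_path, skipped=skipped,
    )


def _phylogeny_order(pop_tree, samples: SampleTable) -> list[str]:
    """Tip order of the rooted population tree, rotated so a landlocked
    population leads (the comparison anchor in every figure analogue)."""
    tips = [l.taxon.label for l in pop_tree.leaf_node_iter()]
    pops = [p for p in tips if p in set(samples.populations())]
    landlocked = samples.landlocked_populations()
    if landlocked and landlocked[0] in pops:
        k = pops.index(landlocked[0])
        pops = pops[k:] + pops[:k]
    for p in samples.populations():
        if p not in pops:
            pops.append(p)
    return pops
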
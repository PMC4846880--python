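"""End-to-end pipeline: scan -> conserve -> co-express -> distributions.

Produces the three nested positional distributions (all scan hits,
conservation-passed hits, hits passing conservation and TF-target
co-expression) plus DHS/ChIP peak distributions, bundled with per-stage
counts in a :class:`RunReport` whose serialized form is byte-identical
across runs with the same inputs and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .conservation import (
    ConservedHit,
    align_promoters,
    assign_orthologs,
    drop_genes_without_full_orthology,
    extract_promoter,
    make_aligner,
    motif_passes_conservation,
    position_shift_distribution,
    test_conservation,
)
from .expression import coexpression_call, filter_expressed, upper_quantile_normalize
from .io_formats import GeneModel, GenomeSet, MotifModel, PeakInterval
from .motif_scan import MotifHit, build_scoring_matrix, exact_pvalues, scan_promoter
from .peaks import (
    annotate_peaks,
    merge_overlapping,
    peak_distribution,
    peak_length_stats,
    per_family_peak_distributions,
)
from .positional_stats import (
    PositionalDistribution,
    build_distribution,
    classify_family,
    cumulative_at,
    dedup_family_sites,
    fraction_in_range,
    hit_position,
    summary_statistics,
)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "ConservationStage",
    "scan_and_conserve",
    "run_full",
    "run_demo",
]


@dataclass
class PipelineConfig:
    """All numeric thresholds of the analysis, at their standard defaults."""

    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    scan_alpha: float = 1e-4
    conservation_tolerance: int = 100
    identity_threshold: float = 50.0
    pcc_threshold: float = 0.8
    expressed_min_rpkm: float = 1.0
    expressed_min_samples: int = 2
    bin_width: int = 50
    family_min_sites: int = 20
    chip_family_min_sites: int = 1000
    seed: int = 0
    reference_species: list[str] = field(
        default_factory=lambda: ["ref1", "ref2", "ref3"]
    )

    def __post_init__(self) -> None:
        for name in (
            "promoter_upstream",
            "promoter_downstream",
            "scan_alpha",
            "conservation_tolerance",
            "identity_threshold",
            "pcc_threshold",
            "expressed_min_rpkm",
            "bin_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def window(self) -> tuple[int, int]:
        return (-self.promoter_upstream, self.promoter_downstream)


def _dist_to_dict(d: PositionalDistribution) -> dict:
    return {
        "label": d.label,
        "n_sites": d.n_sites,
        "peak_position": d.peak_position,
        "kurtosis": d.kurtosis,
        "bin_edges": [float(x) for x in d.bin_edges],
        "density": [float(x) for x in d.density],
        "counts": [int(x) for x in d.counts],
    }


@dataclass
class RunReport:
    config: dict
    counts: dict
    distributions: dict[str, PositionalDistribution]
    cumulative_probes: dict
    fractions: dict
    summary: dict
    family_classes: list[dict]
    shift_distribution: dict
    peak_stats: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "counts": self.counts,
            "distributions": {
                k: _dist_to_dict(v) for k, v in sorted(self.distributions.items())
            },
            "cumulative_probes": self.cumulative_probes,
            "fractions": self.fractions,
            "summary": self.summary,
            "family_classes": self.family_classes,
            "shift_distribution": self.shift_distribution,
            "peak_stats": self.peak_stats,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_path = outdir / "report.json"
        report_path.write_text(self.to_json() + "\n")
        for label, dist in sorted(self.distributions.items()):
            safe = label.replace(":", "_").replace("+", "_")
            with open(outdir / f"distribution_{safe}.tsv", "w") as fh:
                fh.write("bin_start\tbin_end\tcount\tdensity\tcumulative\n")
                cum = 0
                for i in range(len(dist.counts)):
                    cum += int(dist.counts[i])
                    fh.write(
                        f"{dist.bin_edges[i]:.0f}\t{dist.bin_edges[i+1]:.0f}\t"
                        f"{dist.counts[i]}\t{dist.density[i]:.10g}\t"
                        f"{cum / dist.n_sites:.10g}\n"
                    )
        return report_path


@dataclass
class ConservationStage:
    """Scan + conservation results, the shared core of the analysis."""

    retained_genes: list[GeneModel]
    all_hits: list[MotifHit]
    conserved_hits: list[ConservedHit]

    @property
    def passed_hits(self) -> list[MotifHit]:
        return [c.hit for c in self.conserved_hits if c.passed]


def scan_and_conserve(
    config: PipelineConfig,
    genomes: dict[str, GenomeSet],
    genes: dict[str, list[GeneModel]],
    motifs: list[MotifModel],
    ortholog_table: pd.DataFrame,
    query_species: str = "query",
) -> ConservationStage:
    """Scan query promoters and apply the conservation test to every hit.

    Genes lacking a one-to-one ortholog in any reference species are
    dropped before scanning, so the all-hits set and the conserved set
    cover the same genes.
    """
    refs = config.reference_species
    for sp in [query_species, *refs]:
        if sp not in genomes or sp not in genes:
            raise ValueError(f"species {sp!r} missing from genomes/genes")
    query_genes = genes[query_species]
    gene_index = {sp: {g.gene_id: g for g in genes[sp]} for sp in genomes}

    assignments = assign_orthologs(ortholog_table, refs, config.identity_threshold)
    missing = [
        a.ortholog
        for a in assignments.values()
        if a.ortholog is not None and a.ortholog not in gene_index[a.species]
    ]
    if missing:
        raise ValueError(
            f"ortholog ids absent from gene models, e.g. {missing[:3]}"
        )
    retained = drop_genes_without_full_orthology(assignments, refs)
    retained &= set(gene_index[query_species])
    retained_genes = [g for g in query_genes if g.gene_id in retained]

    scoring = []
    for m in motifs:
        sm = build_scoring_matrix(m)
        scoring.append((sm, exact_pvalues(sm)))

    def scan_record(rec) -> list[MotifHit]:
        hits = []
        for sm, pvt in scoring:
            hits.extend(
                scan_promoter(
                    rec.sequence,
                    sm,
                    pvt,
                    alpha=config.scan_alpha,
                    gene_id=rec.gene_id,
                    window_start=rec.window_start,
                )
            )
        return hits

    aligner = make_aligner()
    all_hits: list[MotifHit] = []
    conserved_hits: list[ConservedHit] = []
    for gene in retained_genes:
        q_rec = extract_promoter(
            gene,
            genomes[query_species],
            species=query_species,
            upstream=config.promoter_upstream,
            downstream=config.promoter_downstream,
        )
        q_hits = scan_record(q_rec)
        all_hits.extend(q_hits)
        if not q_hits:
            continue
        ortho_recs = {}
        ortho_hits = {}
        for sp in refs:
            oid = assignments[(gene.gene_id, sp)].ortholog
            orec = extract_promoter(
                gene_index[sp][oid],
                genomes[sp],
                species=sp,
                upstream=config.promoter_upstream,
                downstream=config.promoter_downstream,
            )
            ortho_recs[sp] = orec
            ortho_hits[sp] = scan_record(orec)
        palign = align_promoters(q_rec, ortho_recs, aligner)
        for hit in q_hits:
            ch = test_conservation(
                hit, palign, ortho_hits, tolerance=config.conservation_tolerance
            )
            if ch is not None:
                conserved_hits.append(ch)
    return ConservationStage(retained_genes, all_hits, conserved_hits)


def run_full(
    config: PipelineConfig,
    genomes: dict[str, GenomeSet],
    genes: dict[str, list[GeneModel]],
    motifs: list[MotifModel],
    ortholog_table: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    dhs_peaks: list[PeakInterval] | None = None,
    chip_peaks: list[PeakInterval] | None = None,
    query_species: str = "query",
) -> RunReport:
    """Run the full analysis and return the report.

    ``genomes``/``genes`` map species id -> genome / gene models; the
    query species holds the promoters under study and the configured
    reference species supply the conservation test.  The TF gene of a
    motif is looked up in the expression matrix by the motif's
    ``tf_name``.
    """
    query_genes = genes[query_species]
    family_map = {m.motif_id: m.family for m in motifs}
    tf_of = {m.motif_id: m.tf_name for m in motifs}
    stage = scan_and_conserve(
        config, genomes, genes, motifs, ortholog_table, query_species
    )
    retained_genes = stage.retained_genes
    all_hits = stage.all_hits
    conserved_hits = stage.conserved_hits
    passed_hits = stage.passed_hits

    # co-expression filter on conservation-passed hits
    coexpressed_hits: list[MotifHit] = []
    n_pairs_tested = n_pairs_passed = 0
    if expression is not None:
        expressed = filter_expressed(
            expression, config.expressed_min_rpkm, config.expressed_min_samples
        )
        normalized = upper_quantile_normalize(expression, expressed)
        call_cache: dict[tuple[str, str], bool] = {}
        for hit in passed_hits:
            tf_gene = tf_of[hit.motif_id]
            key = (tf_gene, hit.gene_id)
            if key not in call_cache:
                n_pairs_tested += 1
                if tf_gene not in normalized.index or hit.gene_id not in normalized.index:
                    warnings.warn(
                        f"pair {key} absent from expression matrix; treated as "
                        "not co-expressed"
                    )
                    call_cache[key] = False
                else:
                    call = coexpression_call(
                        tf_gene,
                        hit.gene_id,
                        normalized,
                        threshold=config.pcc_threshold,
                        expressed=expressed,
                    )
                    call_cache[key] = call.passed
                    n_pairs_passed += int(call.passed)
            if call_cache[key]:
                coexpressed_hits.append(hit)

    # distributions over de-duplicated sites (one site per same-family
    # overlapping occurrence cluster per gene)
    window = config.window

    def sites_and_dist(hits: list[MotifHit], label: str):
        by_gene: dict[str, list[MotifHit]] = {}
        for h in hits:
            by_gene.setdefault(h.gene_id, []).append(h)
        sites: list[MotifHit] = []
        for gid in sorted(by_gene):
            sites.extend(dedup_family_sites(by_gene[gid], family_map))
        if not sites:
            return sites, None
        positions = [hit_position(s) for s in sites]
        return sites, build_distribution(
            positions, bin_width=config.bin_width, window=window, label=label
        )

    all_sites, dist_all = sites_and_dist(all_hits, "all_hits")
    cons_sites, dist_cons = sites_and_dist(passed_hits, "conserved")
    coex_sites, dist_coex = sites_and_dist(coexpressed_hits, "conserved+coexpressed")

    distributions: dict[str, PositionalDistribution] = {}
    for d in (dist_all, dist_cons, dist_coex):
        if d is not None:
            distributions[d.label] = d

    # family classification on conserved sites
    family_classes = []
    by_family: dict[str, list[int]] = {}
    for s in cons_sites:
        by_family.setdefault(family_map.get(s.motif_id, "unknown"), []).append(
            hit_position(s)
        )
    for fam in sorted(by_family):
        positions = by_family[fam]
        if len(positions) < config.family_min_sites:
            continue
        fdist = build_distribution(
            positions, bin_width=config.bin_width, window=window,
            label=f"family:{fam}",
        )
        distributions[fdist.label] = fdist
        if fdist.kurtosis is not None:
            fc = classify_family(fam, fdist)
            family_classes.append(asdict(fc))

    # headline probes on the conserved distribution
    cumulative_probes = {}
    fractions = {}
    summary = {}
    if dist_cons is not None:
        cons_positions = [hit_position(s) for s in cons_sites]
        cumulative_probes = {
            str(x): cumulative_at(dist_cons, x) for x in (-1500, -1000, -500)
        }
        fractions = {
            "-1000..+200": fraction_in_range(cons_positions, -1000, 200),
            "-400..+200": fraction_in_range(cons_positions, -400, 200),
        }
        stats = summary_statistics(cons_sites, family_map, len(retained_genes))
        summary = asdict(stats)

    shift_dist = position_shift_distribution(conserved_hits)

    # peaks
    peak_stats: dict = {}
    genome_length = genomes[query_species].total_length()
    if dhs_peaks:
        merged = merge_overlapping(dhs_peaks)
        annotated = annotate_peaks(merged, query_genes)
        stats = peak_length_stats(merged, genome_length)
        dist, n_out = peak_distribution(
            annotated, window=window, bin_width=config.bin_width, label="peaks:DHS"
        )
        distributions[dist.label] = dist
        peak_stats["DHS"] = {**asdict(stats), "n_outside_window": n_out}
    if chip_peaks:
        annotated = annotate_peaks(chip_peaks, query_genes)
        stats = peak_length_stats(chip_peaks, genome_length)
        dist, n_out = peak_distribution(
            annotated, window=window, bin_width=config.bin_width, label="peaks:ChIP"
        )
        distributions[dist.label] = dist
        peak_stats["ChIP"] = {**asdict(stats), "n_outside_window": n_out}
        tf_fam = {m.tf_name: m.family for m in motifs}
        for fam, fdist in per_family_peak_distributions(
            annotated,
            tf_fam,
            min_sites=config.chip_family_min_sites,
            window=window,
            bin_width=config.bin_width,
        ).items():
            distributions[fdist.label] = fdist

    motifs_passed = sum(
        1 for m in motifs if motif_passes_conservation(m.motif_id, conserved_hits)
    )
    counts = {
        "genes_input": len(query_genes),
        "genes_retained": len(retained_genes),
        "genes_with_site": len({s.gene_id for s in cons_sites}),
        "motifs_input": len(motifs),
        "motifs_passed_conservation": motifs_passed,
        "hits_all": len(all_hits),
        "hits_conserved": len(passed_hits),
        "hits_conserved_coexpressed": len(coexpressed_hits),
        "sites_all": len(all_sites),
        "sites_conserved": len(cons_sites),
        "sites_conserved_coexpressed": len(coex_sites),
        "coexpression_pairs_tested": n_pairs_tested,
        "coexpression_pairs_passed": n_pairs_passed,
    }

    return RunReport(
        config=asdict(config),
        counts=counts,
        distributions=distributions,
        cumulative_probes=cumulative_probes,
        fractions=fractions,
        summary=summary,
        family_classes=family_classes,
        shift_distribution=shift_dist,
        peak_stats=peak_stats,
    )


def run_demo(seed: int = 1, outdir=None, spec=None) -> RunReport:
    """Generate the default synthetic dataset and run the full pipeline.

    The demo conditions are the generator defaults (200 genes, 10
    motifs, four species, Gaussian site law at -50 bp); everything is
    deterministic given ``seed``.
    """
    from .synthetic_data import SyntheticSpec, generate_dataset

    if spec is None:
        spec = SyntheticSpec(seed=seed)
    ds = generate_dataset(spec)
    config = PipelineConfig(seed=seed)
    report = run_full(
        config,
        ds.genomes,
        ds.genes,
        ds.motifs,
        ds.ortholog_table,
        expression=ds.expression,
        dhs_peaks=ds.dhs_peaks,
        chip_peaks=ds.chip_peaks,
    )
    if outdir is not None:
        report.write(outdir)
    return report
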
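"""End-to-end orchestration of the cohort analysis.

Stages run in dependency order: annotation -> harmfulness join ->
spectra -> domain statistics -> per-cancer prioritization -> GO/pathway
enrichment -> network degree/module analysis -> cross-cancer overlap.
All thresholds of the analysis (minimum sample count, 95th percentile,
2 % recurrence, 100-sample gate, 20-protein query cutoff, FDR tiers) are
named configuration fields defaulting to the cohort study's values.
Tabular outputs are written per stage; a manifest records input
checksums, the seed, and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import iofmt
from .annotate import annotate_catalog
from .domains import domain_cancer_prevalence, domain_normalized_frequency, top_domains
from .enrich import QueryPolicy, build_query, enrich
from .harmful import join_harmful, load_predictions
from .netanalysis import (
    average_degree,
    cancer_overlap,
    cluster_modules,
    load_sif,
    reduce_network,
)
from .prioritize import (
    SelectionParams,
    normalize_by_length,
    sample_counts,
    select_proteins,
)
from .spectra import build_aas_matrix, build_spectrum

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, message, exit_code=1):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    variants: str
    gff3: str
    reference: str
    predictions: str
    domains: str | None = None
    go_gmt: str | None = None
    pathway_gmt: str | None = None
    network: str | None = None
    cancer_genes: str | None = None
    outdir: str = "results"
    seed: int = 0
    harmful_only_spectra: bool = True
    unique_substitutions: bool = False
    selection: SelectionParams = field(default_factory=SelectionParams)
    policy: QueryPolicy = field(default_factory=QueryPolicy)

    def required_paths(self):
        yield "variants", self.variants
        yield "gff3", self.gff3
        yield "reference", self.reference
        yield "predictions", self.predictions
        for name in ("domains", "go_gmt", "pathway_gmt", "network", "cancer_genes"):
            p = getattr(self, name)
            if p is not None:
                yield name, p


@dataclass
class ResultBundle:
    summary: object
    aas: pd.DataFrame
    harmful: pd.DataFrame
    spectra: dict[str, dict[str, object]]
    aas_matrices: dict[str, object]
    domain_tables: dict[str, pd.DataFrame]
    selections: dict[str, object]
    enrichments: dict[str, dict[str, pd.DataFrame]]
    degrees: dict[str, pd.DataFrame]
    modules: dict[str, dict]
    overlap_networks: tuple | None
    manifest: dict


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema check of every referenced file; returns problem strings."""
    problems = []
    for name, path in config.required_paths():
        if not Path(path).exists():
            problems.append(f"{name}: missing file {path}")
            continue
        try:
            if name == "variants":
                df = iofmt.read_variants(path)
                bad = df.index[~df["ref"].isin(list("ACGT")) | ~df["alt"].isin(list("ACGT"))]
                if len(bad):
                    problems.append(
                        f"variants: non-ACGT allele on data line {int(bad[0]) + 1}"
                    )
            elif name == "gff3":
                iofmt.read_gff3(path)
            elif name == "reference":
                iofmt.read_fasta(path)
            elif name == "predictions":
                load_predictions(path)
            elif name in ("go_gmt", "pathway_gmt"):
                iofmt.read_gmt(path)
            elif name == "network":
                load_sif(path)
        except Exception as exc:  # collect, never raise
            problems.append(f"{name}: {exc}")
    return problems


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute all stages; raises PipelineError(exit_code=2) on missing input."""
    for name, path in config.required_paths():
        if not Path(path).exists():
            raise PipelineError(f"missing input: {path}", exit_code=2)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "inputs": {name: _checksum(path) for name, path in config.required_paths()},
        "stages": {},
    }

    def stage(name, fn):
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        return result

    # ---- load + annotate
    variants = stage("load_variants", lambda: iofmt.read_variants(config.variants))
    models, gene_chrom = stage("load_genes", lambda: iofmt.read_gff3(config.gff3))
    reference = stage("load_reference", lambda: iofmt.read_fasta(config.reference))
    aas, summary = stage(
        "annotate", lambda: annotate_catalog(variants, models, reference, gene_chrom)
    )
    manifest["stages"]["annotate"] = {"n_variants": len(variants), "n_records": len(aas)}
    summary.counts.to_csv(outdir / "annotation_summary.tsv", sep="\t")
    aas.to_csv(outdir / "aas_records.tsv", sep="\t", index=False)

    # ---- harmfulness
    predictions = stage("predictions", lambda: load_predictions(config.predictions))
    harmful = stage("join_harmful", lambda: join_harmful(aas, predictions))
    manifest["stages"]["harmful"] = {"n_harmful": len(harmful)}
    harmful.to_csv(outdir / "harmful_aas.tsv", sep="\t", index=False)

    cancers = sorted(variants["cancer_type"].unique())
    missense = aas[aas["consequence"] == "missense"]

    # ---- spectra + AAS matrices
    spectra: dict[str, dict[str, object]] = {}
    matrices: dict[str, object] = {}
    for cancer in cancers:
        all_m = build_spectrum(missense, cancer)
        harm_m = build_spectrum(harmful, cancer)
        spectra[cancer] = {"all": all_m, "harmful": harm_m}
        all_m.to_frame().to_csv(outdir / f"spectrum_{cancer}_all.tsv", sep="\t", index=False)
        harm_m.to_frame().to_csv(
            outdir / f"spectrum_{cancer}_harmful.tsv", sep="\t", index=False
        )
        matrices[cancer] = build_aas_matrix(
            missense, cancer, unique=config.unique_substitutions
        )
        matrices[cancer].to_frame().to_csv(outdir / f"aas_matrix_{cancer}.tsv", sep="\t")
    manifest["stages"]["spectra"] = {c: spectra[c]["all"].total for c in cancers}

    # ---- domains
    domain_tables: dict[str, pd.DataFrame] = {}
    if config.domains:
        domains = stage("load_domains", lambda: pd.read_csv(config.domains, sep="\t"))
        source = harmful if config.harmful_only_spectra else missense
        for cancer in cancers:
            sub = source[source["cancer_type"] == cancer]
            freq = domain_normalized_frequency(
                sub, domains, unique=config.unique_substitutions
            )
            domain_tables[cancer] = top_domains(freq, 20)
            domain_tables[cancer].to_csv(
                outdir / f"domains_{cancer}.tsv", sep="\t", index=False
            )
        prevalence = domain_cancer_prevalence(source, domains)
        prevalence.to_csv(outdir / "domain_prevalence.tsv", sep="\t")
        domain_tables["prevalence"] = prevalence.to_frame()

    # ---- prioritization
    protein_lengths = pd.Series(
        {m.protein_id: m.protein_length for m in models}
    )
    protein_gene = {m.protein_id: m.gene_id for m in models}
    selections: dict[str, object] = {}
    sel_rows = []
    cancer_genes = (
        iofmt.read_gene_list(config.cancer_genes) if config.cancer_genes else set()
    )
    for cancer in cancers:
        sub = harmful[harmful["cancer_type"] == cancer]
        counts = sample_counts(sub)
        n_samples = int(variants.loc[variants["cancer_type"] == cancer, "sample_id"].nunique())
        sel = select_proteins(counts, n_samples, sub, config.selection, cancer)
        if len(sel.table):
            occ = sub.groupby("protein_id").size().reindex(sel.table["protein_id"]).fillna(0)
            sel.table["normalized_frequency"] = normalize_by_length(
                occ, protein_lengths
            ).to_numpy()
            genes = [protein_gene.get(p, p) for p in sel.table["protein_id"]]
            sel.table["gene_id"] = genes
            sel.table["in_known_list"] = [g in cancer_genes for g in genes]
        selections[cancer] = sel
        sel_rows.append((cancer, len(sel.table), sel.threshold, sel.n_samples_with_harmful))
        sel.table.to_csv(outdir / f"selection_{cancer}.tsv", sep="\t", index=False)
    manifest["stages"]["selection"] = {
        c: int(len(selections[c].table)) for c in cancers
    }

    # ---- enrichment; universe = all annotated genes (plus any set member)
    enrichments: dict[str, dict[str, pd.DataFrame]] = {}
    all_genes = {m.gene_id for m in models}

    def read_collection(path):
        coll = iofmt.read_gmt(path)
        universe = frozenset(all_genes | set(coll.universe))
        return type(coll)(sets=coll.sets, universe=universe)

    go = read_collection(config.go_gmt) if config.go_gmt else None
    pathways = read_collection(config.pathway_gmt) if config.pathway_gmt else None
    sig_pathways: dict[str, set] = {}
    selected_genes: dict[str, set] = {}
    for cancer in cancers:
        sel = selections[cancer]
        sel_genes = {protein_gene.get(p, p) for p in sel.proteins}
        selected_genes[cancer] = sel_genes
        harm_genes = {
            protein_gene.get(p, p)
            for p in harmful.loc[harmful["cancer_type"] == cancer, "protein_id"]
        }
        query, go_tier = build_query(sel_genes, harm_genes, config.policy)
        enrichments[cancer] = {}
        if go is not None:
            res = enrich(query, go, fdr=go_tier)
            enrichments[cancer]["go"] = res
            res.to_csv(outdir / f"go_{cancer}.tsv", sep="\t", index=False)
        if pathways is not None:
            res = enrich(query, pathways, fdr=config.policy.pathway_fdr)
            enrichments[cancer]["pathway"] = res
            res.to_csv(outdir / f"pathways_{cancer}.tsv", sep="\t", index=False)
            sig_pathways[cancer] = set(res.loc[res["significant"], "term"])

    # ---- network analysis
    degrees: dict[str, pd.DataFrame] = {}
    modules: dict[str, dict] = {}
    if config.network:
        net = stage("load_network", lambda: load_sif(config.network))
        whole = average_degree(list(net.nodes), net)
        for cancer in cancers:
            sel_genes = selected_genes[cancer]
            harm_genes = {
                protein_gene.get(p, p)
                for p in harmful.loc[harmful["cancer_type"] == cancer, "protein_id"]
            }
            rows = [("whole_network", whole.n, whole.e_n, whole.e_other, whole.average_degree)]
            for name, nodes in (
                ("selected", sel_genes),
                ("other_harmful", harm_genes - sel_genes),
            ):
                present = set(nodes) & set(net.nodes)
                if present:
                    s = average_degree(present, net)
                    rows.append((name, s.n, s.e_n, s.e_other, s.average_degree))
            degrees[cancer] = pd.DataFrame(
                rows, columns=["node_set", "n", "e_n", "e_other", "average_degree"]
            )
            degrees[cancer].to_csv(outdir / f"degrees_{cancer}.tsv", sep="\t", index=False)
            sub = reduce_network(net, sel_genes, harm_genes)
            if sub.number_of_nodes():
                modules[cancer] = cluster_modules(sub, seed=config.seed)

    overlap = None
    if sig_pathways and len(sig_pathways) >= 2:
        overlap = cancer_overlap(
            sig_pathways, selected_genes, split_cutoff=config.policy.selection_cutoff
        )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return ResultBundle(
        summary=summary,
        aas=aas,
        harmful=harmful,
        spectra=spectra,
        aas_matrices=matrices,
        domain_tables=domain_tables,
        selections=selections,
        enrichments=enrichments,
        degrees=degrees,
        modules=modules,
        overlap_networks=overlap,
        manifest=manifest,
    )
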
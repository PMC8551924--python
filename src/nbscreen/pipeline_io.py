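"""Orchestration, configuration and file formats.

Every on-disk artifact is plain text: TSV matrices/tables, a plate CSV, a
minimal VCF for variants, edge-list TSV / GraphML for networks, and a JSON run
manifest recording the config snapshot, seeds, file digests and stage counts.
All writers/readers round-trip losslessly; malformed inputs raise ParseError
with the offending location rather than being silently coerced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage

from . import association_screen as assoc
from . import drug_screen as ds
from . import pathway_network as pathway
from . import synthetic_cohort as synth
from .genomic_profiling import (
    CopyNumberProfile,
    FilterCriteria,
    VariantRecord,
    core_panel,
    exclude_population_snps,
    filter_somatic_variants,
    panel_frame,
    segment_probes_to_genes,
)

__all__ = [
    "ParseError",
    "RunConfig",
    "load_config",
    "write_probe_table", "read_probe_table",
    "write_plates_csv", "read_plates_csv",
    "write_vcf", "read_vcf",
    "write_drug_library", "read_drug_library",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_association_table", "read_association_table",
    "write_edge_list", "read_edge_list",
    "write_graphml",
    "write_manifest", "read_manifest",
    "hierarchical_cluster_order",
    "run_all",
    "simulate_stage", "profile_stage", "screen_stage", "associate_stage",
    "network_stage",
]

log = logging.getLogger("nbscreen")


class ParseError(ValueError):
    """Malformed input file; message names the file/line/field."""


# ---------------------------------------------------------------------------
# tabular formats (all tab-separated with header rows; missing = empty field)

def write_probe_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    for col in ("probe_id", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: probe table missing column {col!r}")
    return df


def write_plates_csv(plates: Sequence[ds.PlateReadings], path) -> None:
    frames = []
    for p in plates:
        df = p.wells.copy()
        df.insert(0, "sample_id", p.sample_id)
        df.insert(0, "plate_id", p.plate_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plates_csv(path) -> list[ds.PlateReadings]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"plate_id", "sample_id", "well", "compound_id", "rlu"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: plate CSV missing columns {sorted(missing)}")
    plates = []
    for (pid, sid), grp in df.groupby(["plate_id", "sample_id"], sort=False):
        wells = grp[["well", "compound_id", "rlu"]].reset_index(drop=True)
        try:
            plates.append(ds.PlateReadings(str(pid), str(sid), wells))
        except ds.PlateError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return plates


def write_drug_library(library: pd.DataFrame, path) -> None:
    library.to_csv(path, sep="\t", index=False)


def read_drug_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    required = {"compound_id", "mechanism_class", "target_genes"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: drug library missing columns {sorted(missing)}")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path, index_name: str = "id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df


def write_association_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_association_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"gene_id", "drug_id", "n", "r", "z", "p", "q", "significant"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: association table missing columns {sorted(missing)}")
    return df


def write_edge_list(graph: nx.Graph, path, weight: str = "fi_weight") -> None:
    rows = [
        {"gene_a": u, "gene_b": v, weight: d[weight]}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", weight]).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> nx.Graph:
    try:
        return pathway.load_fi_network(path)
    except pathway.NetworkError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_graphml(graph: nx.Graph, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(
        (n, {k: v for k, v in d.items() if v is not None and v == v})
        for n, d in graph.nodes(data=True)
    )
    g.add_edges_from((u, v, d) for u, v, d in graph.edges(data=True))
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# minimal VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=nbscreen
##INFO=<ID=SM,Number=1,Type=String,Description="Sample ID">
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">
##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Reported in COSMIC">
##INFO=<ID=POPFREQ,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=PSNP,Number=0,Type=Flag,Description="Recurrent population SNP">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: Sequence[VariantRecord], path) -> None:
    """Serialize variant records as a minimal single-column VCF."""
    head, last = _VCF_HEADER.rsplit("#CHROM", 1)
    lines = [head]
    lines.extend(f"##contig=<ID={c}>\n" for c in sorted({v.chrom for v in variants}))
    lines.append("#CHROM" + last)
    for v in sorted(variants, key=lambda r: (r.sample_id, r.chrom, r.pos)):
        info = (
            f"SM={v.sample_id};GENE={v.gene_id};DP={v.coverage};"
            f"AF={v.allele_fraction!r};POPFREQ={v.population_frequency!r}"
        )
        if v.cosmic_reported:
            info += ";COSMIC"
        if v.is_population_snp:
            info += ";PSNP"
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf(path) -> list[VariantRecord]:
    """Parse a minimal VCF back into variant records (via cyvcf2)."""
    from cyvcf2 import VCF

    records = []
    for var in VCF(str(path)):
        info = dict(var.INFO)
        for key in ("SM", "GENE", "DP", "AF", "POPFREQ"):
            if key not in info:
                raise ParseError(
                    f"{path}: record {var.CHROM}:{var.POS} missing INFO key {key}"
                )
        records.append(
            VariantRecord(
                sample_id=str(info["SM"]),
                gene_id=str(info["GENE"]),
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref=str(var.REF),
                alt=str(var.ALT[0]) if var.ALT else "N",
                coverage=int(info["DP"]),
                allele_fraction=float(np.atleast_1d(info["AF"])[0]),
                cosmic_reported="COSMIC" in info,
                population_frequency=float(info["POPFREQ"]),
                is_population_snp="PSNP" in info,
            )
        )
    return records


# ---------------------------------------------------------------------------
# manifest and config

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass(frozen=True)
class RunConfig:
    """Whole-pipeline configuration (per-stage sections)."""

    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    screen: assoc.ScreenConfig = field(default_factory=assoc.ScreenConfig)
    hits: ds.HitCallConfig = field(default_factory=ds.HitCallConfig)
    permutations: pathway.PermutationConfig = field(default_factory=pathway.PermutationConfig)
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    coupling_scale: float = 1.0
    use_core_panel: bool = True  # drop quiet genes before the association screen
    focus_drugs: tuple[str, ...] = ("Sunitinib", "Vandetanib")


def load_config(path) -> RunConfig:
    """Read a YAML config with optional per-stage sections.

    Unknown keys are rejected; omitted sections keep their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sections = {
        "cohort": synth.CohortConfig,
        "screen": assoc.ScreenConfig,
        "hits": ds.HitCallConfig,
        "permutations": pathway.PermutationConfig,
        "filter_criteria": FilterCriteria,
    }
    kwargs = {}
    for name, cls in sections.items():
        entries = raw.pop(name, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(entries) - valid
        if bad:
            raise ParseError(f"{path}: unknown key(s) in [{name}]: {sorted(bad)}")
        if name == "cohort" and "planted_pairs" in entries:
            entries["planted_pairs"] = tuple(
                synth.PlantedPair(*p) for p in entries["planted_pairs"]
            )
        if name == "cohort" and "arm_event_rates" in entries:
            entries["arm_event_rates"] = tuple(
                synth.ArmEvent(*e) for e in entries["arm_event_rates"]
            )
        kwargs[name] = cls(**entries)
    for key in ("coupling_scale", "use_core_panel", "focus_drugs"):
        if key in raw:
            val = raw.pop(key)
            kwargs[key] = tuple(val) if key == "focus_drugs" else val
    if raw:
        raise ParseError(f"{path}: unknown top-level key(s): {sorted(raw)}")
    return RunConfig(**kwargs)


def _config_snapshot(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(x) for x in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    snap = enc(cfg)
    # the panel is summarized by digest-able content, not serialized in full
    snap["cohort"]["panel"] = {
        "n_genes": len(cfg.cohort.panel),
        "n_probes": int(sum(len(g.probe_ids) for g in cfg.cohort.panel)),
    }
    return snap


# ---------------------------------------------------------------------------
# hierarchical clustering for heatmap ordering

def hierarchical_cluster_order(
    matrix: pd.DataFrame, method: str = "complete", metric: str = "euclidean"
) -> dict:
    """Agglomerative row/column orderings (complete linkage, Euclidean).

    Returns row/col leaf orders plus the linkage matrices (as lists) so the
    dendrogram and any heatmap drawn from it are reproducible. Non-finite
    entries are an error listing the offending cells.
    """
    arr = matrix.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if len(bad):
        cells = [f"({matrix.index[i]}, {matrix.columns[j]})" for i, j in bad[:5]]
        raise ParseError(f"non-finite entries at {', '.join(cells)}")

    def order(data: np.ndarray):
        if data.shape[0] < 2:
            return list(range(data.shape[0])), []
        lk = linkage(data, method=method, metric=metric)
        return [int(i) for i in leaves_list(lk)], lk.tolist()

    row_order, row_linkage = order(arr)
    col_order, col_linkage = order(arr.T)
    return {
        "row_order": [str(matrix.index[i]) for i in row_order],
        "col_order": [str(matrix.columns[j]) for j in col_order],
        "row_linkage": row_linkage,
        "col_linkage": col_linkage,
    }


# ---------------------------------------------------------------------------
# stages

def _stage_timer(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def simulate_stage(cfg: RunConfig, out: Path, seed: int) -> synth.Cohort:
    """Generate a cohort and serialize it under out/cohort/."""
    with _stage_timer("simulate"):
        cohort = synth.generate_cohort(cfg.cohort, seed)
        d = out / "cohort"
        d.mkdir(parents=True, exist_ok=True)
        write_probe_table(cohort.probe_table, d / "probes.tsv")
        write_plates_csv(cohort.plates, d / "plates.csv")
        write_vcf(cohort.variants, d / "variants.vcf")
        write_drug_library(cohort.drug_library, d / "drug_library.tsv")
        write_matrix_tsv(cohort.truth.true_copies, d / "truth_copies.tsv", "gene_id")
        write_matrix_tsv(cohort.latent_cytotoxicity, d / "truth_latent_cytotoxicity.tsv",
                         "compound_id")
        panel_frame(list(cfg.cohort.panel)).to_csv(d / "panel.tsv", sep="\t", index=False)
        events = pd.DataFrame(
            [
                {"sample_id": s, "arm": arm, "event": ev}
                for s, evs in cohort.truth.arm_events.items()
                for arm, ev in evs
            ],
            columns=["sample_id", "arm", "event"],
        )
        events.to_csv(d / "truth_arm_events.tsv", sep="\t", index=False)
        planted = pd.DataFrame(
            [dataclasses.asdict(p) for p in cohort.truth.planted_pairs],
            columns=["gene_id", "drug_id", "slope"],
        )
        planted.to_csv(d / "truth_planted_pairs.tsv", sep="\t", index=False)
        return cohort


@dataclass
class StageData:
    """In-memory bundle passed between stages."""

    probe_table: pd.DataFrame
    plates: list
    variants: list
    drug_library: pd.DataFrame
    profile: CopyNumberProfile | None = None
    cytotox: ds.CytotoxicityMatrix | None = None
    associations: pd.DataFrame | None = None
    venn: dict | None = None
    impact: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)


def ingest_stage(cohort_dir: Path) -> StageData:
    """Load a previously serialized cohort directory."""
    d = Path(cohort_dir)
    return StageData(
        probe_table=read_probe_table(d / "probes.tsv"),
        plates=read_plates_csv(d / "plates.csv"),
        variants=read_vcf(d / "variants.vcf"),
        drug_library=read_drug_library(d / "drug_library.tsv"),
    )


def profile_stage(cfg: RunConfig, data: StageData, out: Path) -> StageData:
    """Probe segmentation + variant filtering -> out/profile/."""
    with _stage_timer("profile"):
        d = out / "profile"
        d.mkdir(parents=True, exist_ok=True)
        panel = list(cfg.cohort.panel)
        profile = segment_probes_to_genes(data.probe_table, panel)
        if cfg.use_core_panel:
            keep = [g.gene_id for g in core_panel(panel, cfg.cohort.quiet_genes)
                    if g.gene_id in profile.log2_ratio.index]
            profile = CopyNumberProfile(
                profile.log2_ratio.loc[keep], profile.ploidy, profile.dropped_genes
            )
        write_matrix_tsv(profile.log2_ratio, d / "gene_log2_ratio.tsv", "gene_id")
        remaining, snps = exclude_population_snps(data.variants)
        passing, rejected = filter_somatic_variants(remaining, cfg.filter_criteria)
        report = pd.DataFrame(
            [
                {"variant_id": r.variant_id, "status": "population_snp", "reasons": ""}
                for r in snps
            ]
            + [
                {"variant_id": r.variant_id, "status": "pass", "reasons": ""}
                for r in passing
            ]
            + [
                {"variant_id": r.variant_id, "status": "rejected",
                 "reasons": ";".join(why)}
                for r, why in rejected
            ],
            columns=["variant_id", "status", "reasons"],
        )
        report.sort_values("variant_id").to_csv(
            d / "variant_filter_report.tsv", sep="\t", index=False
        )
        data.profile = profile
        data.counts.update(
            n_variants_input=len(data.variants),
            n_population_snps=len(snps),
            n_variants_pass=len(passing),
            n_variants_rejected=len(rejected),
            n_genes_profiled=len(profile.genes),
        )
        return data


def screen_stage(cfg: RunConfig, data: StageData, out: Path) -> StageData:
    """Plate normalization/QC, hit calling, class summary -> out/screen/."""
    with _stage_timer("screen"):
        d = out / "screen"
        d.mkdir(parents=True, exist_ok=True)
        classes = data.drug_library.set_index("compound_id")["mechanism_class"]
        cyto = ds.build_cytotoxicity_matrix(data.plates, cfg.hits, classes)
        write_matrix_tsv(cyto.values, d / "cytotoxicity.tsv", "compound_id")
        cyto.qc.to_csv(d / "plate_qc.tsv", sep="\t", index=False)
        hits = ds.call_hits(cyto, cfg.hits)
        hits.to_csv(d / "hits.tsv", sep="\t", index=False)
        ds.summarize_by_class(cyto).to_csv(d / "class_summary.tsv", sep="\t", index=False)
        clust = hierarchical_cluster_order(cyto.values.dropna(axis=1, how="all").fillna(0.0))
        Path(d / "cytotoxicity_cluster_order.json").write_text(
            json.dumps({k: clust[k] for k in ("row_order", "col_order")}, indent=2) + "\n"
        )
        data.cytotox = cyto
        data.counts.update(
            n_plates=len(data.plates),
            n_plates_qc_pass=int(cyto.qc["passed"].sum()),
            n_hits=len(hits),
        )
        return data


def associate_stage(cfg: RunConfig, data: StageData, out: Path) -> StageData:
    """All-pairs association screen + venn + ranking -> out/associate/."""
    with _stage_timer("associate"):
        d = out / "associate"
        d.mkdir(parents=True, exist_ok=True)
        table = assoc.run_screen(data.profile, data.cytotox, cfg.screen)
        expected = synth.expected_pairs(data.drug_library)
        table, venn = assoc.classify_against_expected(table, expected)
        table = assoc.rank_by_effect(table, data.cytotox.drug_means)
        write_association_table(table, d / "associations.tsv")
        Path(d / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        data.associations = table
        data.venn = venn
        data.counts.update(
            pairs_enumerated=len(table),
            pairs_testable=int(table["testable"].sum()),
            pairs_significant=int(table["significant"].sum()),
            venn=venn,
        )
        return data


def network_stage(cfg: RunConfig, data: StageData, out: Path, seed: int) -> StageData:
    """MRF impact scoring, drug overlay, z-score network, clustering,
    first-degree-neighbor comparison -> out/network/."""
    with _stage_timer("network"):
        d = out / "network"
        d.mkdir(parents=True, exist_ok=True)
        panel = list(cfg.cohort.panel)
        fi = pathway.synthetic_fi_network(panel, seed=seed)
        write_edge_list(fi, d / "fi_edges.tsv")
        perm = dataclasses.replace(cfg.permutations, seed=seed)
        impact = pathway.impact_scores(
            fi, data.profile, perm, coupling_scale=cfg.coupling_scale
        )
        impact.reset_index().to_csv(d / "impact_scores.tsv", sep="\t", index=False)
        selected = pathway.select_impacted_genes(impact)

        name_of = data.drug_library.set_index("compound_id")["name"].to_dict()
        targets = {
            row.compound_id: [g for g in str(row.target_genes).split(";") if g]
            for row in data.drug_library.itertuples(index=False)
        }
        gene_graph = fi.subgraph(selected).copy()
        for g in gene_graph.nodes:
            gene_graph.nodes[g]["kind"] = "gene"
            gene_graph.nodes[g]["impact_diff"] = float(impact.loc[g, "diff"])
        pgm_net = pathway.overlay_drugs(
            gene_graph, {c: t for c, t in targets.items() if t}
        )
        write_graphml(pgm_net, d / "pgm_network.graphml")

        z_net = pathway.build_zscore_network(data.associations, data.cytotox.drug_means)
        write_graphml(z_net, d / "zscore_network.graphml")

        assignment, modules = pathway.cluster_subnetworks(pgm_net) \
            if pgm_net.number_of_nodes() else ({}, pd.DataFrame())
        modules.to_csv(d / "modules.tsv", sep="\t", index=False)

        focus = [c for c in cfg.focus_drugs]
        # focus drugs may be given by display name
        by_name = {v: k for k, v in name_of.items()}
        focus = [by_name.get(f, f) for f in focus]
        comparison = pathway.compare_networks(pgm_net, z_net, focus) \
            if focus else pd.DataFrame()
        comparison.to_csv(d / "network_comparison.tsv", sep="\t", index=False)

        data.impact = impact
        data.counts.update(
            n_genes_scored=len(impact),
            n_genes_selected=len(selected),
            n_zscore_edges=z_net.number_of_edges(),
            n_modules=len(modules),
        )
        return data


def run_all(
    cfg: RunConfig, out, seed: int, ingest_dir=None
) -> dict:
    """Execute simulate (or ingest) -> profile -> screen -> associate ->
    network; write the manifest last. Returns the manifest dict."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if ingest_dir is None:
        cohort = simulate_stage(cfg, out, seed)
        data = StageData(
            probe_table=cohort.probe_table, plates=cohort.plates,
            variants=cohort.variants, drug_library=cohort.drug_library,
        )
        mode = "simulate"
    else:
        data = ingest_stage(Path(ingest_dir))
        mode = "ingest"
    data = profile_stage(cfg, data, out)
    data = screen_stage(cfg, data, out)
    data = associate_stage(cfg, data, out)
    data = network_stage(cfg, data, out, seed)

    digests = {
        str(p.relative_to(out)): _digest(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "tool": "nbscreen",
        "mode": mode,
        "seed": seed,
        "config": _config_snapshot(cfg),
        "counts": data.counts,
        "files": digests,
    }
    write_manifest(manifest, out / "manifest.json")
    return manifest


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
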
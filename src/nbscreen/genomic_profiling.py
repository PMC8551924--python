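"""Gene-level copy-number profiles and somatic-variant filtering.

Probe-level log2 ratios from a targeted panel are segmented (averaged) into a
gene x sample log2-ratio matrix; log ratios convert to absolute copies as
``copies = ploidy * 2**log2_ratio``. Raw variant records are filtered with the
standard coverage / allele-fraction / COSMIC / population-frequency criteria,
and recurrent population SNPs can be excluded by flag or by ID list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneLocus",
    "CopyNumberProfile",
    "VariantRecord",
    "FilterCriteria",
    "PanelError",
    "ProfileInputError",
    "QUIET_GENES",
    "load_panel",
    "default_panel",
    "core_panel",
    "panel_frame",
    "segment_probes_to_genes",
    "log_ratio_to_copies",
    "filter_somatic_variants",
    "exclude_population_snps",
]

#: Panel genes in which the generator never places a copy-number event; the
#: downstream screen therefore runs on the remaining 131 genes.
QUIET_GENES = ("FASLG", "NF2", "NRAS", "SETBP1", "SMARCB1")


class PanelError(ValueError):
    """Malformed gene panel definition."""


class ProfileInputError(ValueError):
    """Malformed probe matrix or variant input."""


@dataclass(frozen=True)
class GeneLocus:
    """A panel gene: symbol, chromosome, arm, and its probes."""

    gene_id: str
    chrom: str
    arm: str  # "p" or "q"
    probe_ids: tuple[str, ...]

    @property
    def arm_name(self) -> str:
        return f"{self.chrom}{self.arm}"

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise PanelError(f"{self.gene_id}: arm must be 'p' or 'q', got {self.arm!r}")
        if len(self.probe_ids) < 1:
            raise PanelError(f"{self.gene_id}: a gene needs at least one probe")


def _make_loci(rows: Iterable[tuple[str, str, str, int]]) -> list[GeneLocus]:
    loci = []
    seen: set[str] = set()
    for gene, chrom, arm, n_probes in rows:
        if gene in seen:
            raise PanelError(f"duplicate gene in panel: {gene}")
        seen.add(gene)
        probes = tuple(f"{gene}_p{i:02d}" for i in range(int(n_probes)))
        loci.append(GeneLocus(gene, str(chrom), arm, probes))
    return loci


def load_panel(path) -> list[GeneLocus]:
    """Load a panel from a TSV with columns gene_id, chrom, arm, n_probes."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "arm", "n_probes"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    return _make_loci(df[["gene_id", "chrom", "arm", "n_probes"]].itertuples(index=False))


def default_panel() -> list[GeneLocus]:
    """The bundled synthetic 136-gene panel (2998 probes)."""
    with resources.files("nbscreen.data").joinpath("default_panel.tsv").open("rb") as fh:
        return load_panel(fh)


def core_panel(panel: Sequence[GeneLocus] | None = None,
               exclude: Iterable[str] = QUIET_GENES) -> list[GeneLocus]:
    """Panel restricted to genes that can carry CNV signal (136 -> 131)."""
    if panel is None:
        panel = default_panel()
    drop = set(exclude)
    return [g for g in panel if g.gene_id not in drop]


def panel_frame(panel: Sequence[GeneLocus]) -> pd.DataFrame:
    """Panel as a tidy frame (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in panel],
            "chrom": [g.chrom for g in panel],
            "arm": [g.arm for g in panel],
            "n_probes": [len(g.probe_ids) for g in panel],
        }
    )


@dataclass
class CopyNumberProfile:
    """Gene x sample log2-ratio matrix with its absolute-copy view."""

    log2_ratio: pd.DataFrame  # index: gene_id, columns: sample_id
    ploidy: float = 2.0
    dropped_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_ratio.to_numpy(dtype=float)).all():
            raise ProfileInputError("log2 ratios must be finite")

    @property
    def copies(self) -> pd.DataFrame:
        return log_ratio_to_copies(self.log2_ratio, self.ploidy)

    @property
    def genes(self) -> list[str]:
        return list(self.log2_ratio.index)

    @property
    def samples(self) -> list[str]:
        return list(self.log2_ratio.columns)


def segment_probes_to_genes(probe_table: pd.DataFrame,
                            panel: Sequence[GeneLocus],
                            ploidy: float = 2.0) -> CopyNumberProfile:
    """Average probe log2 ratios into gene-level log2 ratios.

    ``probe_table`` needs columns probe_id and gene_id plus one column per
    sample. Genes whose probes are all missing are dropped and recorded in
    ``dropped_genes``; a probe naming an unknown gene is an error.
    """
    meta_cols = [c for c in ("probe_id", "gene_id", "chrom", "arm") if c in probe_table.columns]
    if "probe_id" not in meta_cols or "gene_id" not in meta_cols:
        raise ProfileInputError("probe table needs 'probe_id' and 'gene_id' columns")
    sample_cols = [c for c in probe_table.columns if c not in meta_cols]
    if not sample_cols:
        raise ProfileInputError("probe table has no sample columns")

    known = {g.gene_id for g in panel}
    bad = probe_table.loc[~probe_table["gene_id"].isin(known), "probe_id"]
    if len(bad):
        raise ProfileInputError(
            f"probe(s) reference unknown gene(s): {', '.join(map(str, bad.head(5)))}"
        )

    means = probe_table.groupby("gene_id", sort=False)[sample_cols].mean()
    order = [g.gene_id for g in panel if g.gene_id in means.index]
    means = means.reindex(order)

    # only genes present in the table but with no usable probe values are
    # "dropped"; genes absent from a partial table are simply not profiled
    usable = means.notna().all(axis=1)
    dropped = tuple(sorted(set(means.index) - set(means.index[usable])))
    if dropped:
        warnings.warn(f"dropping genes with no usable probes: {dropped}", stacklevel=2)
    return CopyNumberProfile(means.loc[usable], ploidy=ploidy, dropped_genes=dropped)


def log_ratio_to_copies(log2_ratio, ploidy: float = 2.0):
    """copies = ploidy * 2**log2_ratio (elementwise; works on scalars/frames)."""
    if isinstance(log2_ratio, pd.DataFrame):
        return ploidy * np.exp2(log2_ratio.astype(float))
    return ploidy * np.exp2(np.asarray(log2_ratio, dtype=float))


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/indel candidate call."""

    sample_id: str
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    coverage: int
    allele_fraction: float
    cosmic_reported: bool
    population_frequency: float
    is_population_snp: bool = False

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ProfileInputError(f"{self.variant_id}: coverage must be >= 0")
        for name in ("allele_fraction", "population_frequency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ProfileInputError(f"{self.variant_id}: {name} out of [0, 1]: {v}")

    @property
    def variant_id(self) -> str:
        return f"{self.sample_id}:{self.gene_id}:{self.pos}"


@dataclass(frozen=True)
class FilterCriteria:
    """Somatic SNV candidate criteria.

    A record passes iff coverage > min_coverage (strict), allele fraction >=
    min_allele_fraction (inclusive), COSMIC-reported when required, and
    population frequency < max_population_frequency (strict).
    """

    min_coverage: int = 100
    min_allele_fraction: float = 0.10
    require_cosmic: bool = True
    max_population_frequency: float = 0.01


def filter_somatic_variants(
    records: Iterable[VariantRecord],
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, tuple[str, ...]]]]:
    """Split records into (passing, rejected-with-all-failed-criteria)."""
    passing: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, tuple[str, ...]]] = []
    for rec in records:
        reasons = []
        if not rec.coverage > criteria.min_coverage:
            reasons.append("coverage")
        if not rec.allele_fraction >= criteria.min_allele_fraction:
            reasons.append("allele_fraction")
        if criteria.require_cosmic and not rec.cosmic_reported:
            reasons.append("cosmic")
        if not rec.population_frequency < criteria.max_population_frequency:
            reasons.append("population_frequency")
        if reasons:
            rejected.append((rec, tuple(reasons)))
        else:
            passing.append(rec)
    return passing, rejected


def exclude_population_snps(
    records: Sequence[VariantRecord],
    snp_ids: Iterable[str] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Drop recurrent population SNPs, by record flag or explicit ID list.

    Returns (remaining, excluded); |in| == |remaining| + |excluded|.
    """
    id_set = set(snp_ids) if snp_ids is not None else None
    remaining, excluded = [], []
    for rec in records:
        flagged = rec.variant_id in id_set if id_set is not None else rec.is_population_snp
        (excluded if flagged else remaining).append(rec)
    return remaining, excluded
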
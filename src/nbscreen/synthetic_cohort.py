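"""Synthetic tumor-cohort generator with ground truth.

Emulates the statistical structure the downstream analysis assumes: a small
cohort (13 samples) profiled on a 136-gene / ~3000-probe panel with arm-level
segmental aberrations (1p loss, 11q loss, 17q gain) plus focal MYCN-style
amplification; a 418-compound single-dose screen read out as per-plate RLU with
DMSO and staurosporine controls; and sparse somatic variant records. Planted
gene-drug effects (cytotoxicity linear in copy number) and the exhaustive null
set are recorded in a truth table so false-discovery and power properties can
be measured exactly.

All randomness flows from one root seed through fixed labeled child streams
(see `_rng`), so the same seed reproduces the cohort byte-for-byte and adding
drugs does not perturb the copy-number draws.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .drug_screen import DMSO, STAUROSPORINE, PlateReadings
from .genomic_profiling import (
    GeneLocus,
    QUIET_GENES,
    VariantRecord,
    default_panel,
)

__all__ = [
    "ArmEvent",
    "PlantedPair",
    "CohortConfig",
    "SyntheticTruth",
    "Cohort",
    "ConfigError",
    "default_drug_library",
    "expected_pairs",
    "generate_copy_number",
    "generate_drug_response",
    "generate_variants",
    "generate_cohort",
    "planted_pairs_for_target_r",
]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class ArmEvent:
    arm: str  # e.g. "17q"
    event: str  # "loss" | "gain"
    probability: float

    def __post_init__(self) -> None:
        if self.event not in ("loss", "gain"):
            raise ConfigError(f"{self.arm}: event must be 'loss' or 'gain'")
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigError(f"{self.arm}: probability out of [0, 1]")

    @property
    def shift(self) -> int:
        return -1 if self.event == "loss" else 1


@dataclass(frozen=True)
class PlantedPair:
    """A true gene-drug effect: cytotoxicity-% gained per extra gene copy."""

    gene_id: str
    drug_id: str
    slope: float


#: Arm-level event rates observed in the emulated cohort.
DEFAULT_ARM_EVENTS = (
    ArmEvent("1p", "loss", 0.31),
    ArmEvent("11q", "loss", 0.38),
    ArmEvent("17q", "gain", 0.69),
)

#: Mechanism classes used by the bundled drug library.
DRUG_CLASSES = (
    "PI3K/Akt/mTOR",
    "Cell Cycle",
    "JAK/STAT",
    "Protein T.K.",
    "Angiogenesis",
    "Epigenetics",
    "DNA Damage",
    "Apoptosis",
    "NF-KB",
    "MAPK",
    "TGF-beta/Smad",
    "Metabolism",
)

_NAMED_COMPOUNDS = (
    ("BGT226", "PI3K/Akt/mTOR"),
    ("P276-00", "Cell Cycle"),
    ("PIK-75", "PI3K/Akt/mTOR"),
    ("Tivantinib", "Protein T.K."),
    ("Flavopiridol", "Cell Cycle"),
    ("Flavopiridol-HCl", "Cell Cycle"),
    ("SNS-032", "Cell Cycle"),
    ("Dinaciclib", "Cell Cycle"),
    ("AT7519", "Cell Cycle"),
    ("INK128", "PI3K/Akt/mTOR"),
    ("PI-103", "PI3K/Akt/mTOR"),
    ("AT9283", "JAK/STAT"),
    ("KX2-391", "Angiogenesis"),
    ("HS-173", "PI3K/Akt/mTOR"),
    ("IMD-0354", "NF-KB"),
    ("Saracatinib", "Protein T.K."),
    ("Sunitinib", "Protein T.K."),
    ("Vandetanib", "Protein T.K."),
    ("Volasertib", "Cell Cycle"),
    ("Palbociclib", "Cell Cycle"),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the emulated study: 13 samples, the 136-gene bundled
    panel, arm-event rates (1p loss 0.31, 11q loss 0.38, 17q gain 0.69), focal
    MYCN amplification to 10-40 copies in 23% of samples, a 418-compound
    library, and a Poisson(3.1) somatic variant load per sample.
    """

    n_samples: int = 13
    panel: tuple[GeneLocus, ...] = field(default_factory=lambda: tuple(default_panel()))
    arm_event_rates: tuple[ArmEvent, ...] = DEFAULT_ARM_EVENTS
    focal_amp_gene: str = "MYCN"
    focal_amp_probability: float = 0.23
    focal_amp_copy_range: tuple[float, float] = (10.0, 40.0)
    quiet_genes: tuple[str, ...] = QUIET_GENES
    probe_noise_sd: float = 0.1  # log2-ratio units
    n_drugs: int = 418
    planted_pairs: tuple[PlantedPair, ...] = ()
    baseline_potency: tuple[float, float] = (15.0, 18.0)  # Normal(mean, sd), % units
    response_noise_sd: float = 5.0  # % cytotoxicity units
    mutation_rate: float = 3.1  # mean somatic variants per sample
    # plate layout / readout
    rlu_scale: float = 1e6
    n_replicate_wells: int = 3
    n_dmso_wells: int = 8
    n_stauro_wells: int = 4
    well_noise_cv: float = 0.02
    stauro_viability: float = 0.043  # residual viability => ~95.7% cytotoxicity
    # variant-record composition: fraction of candidates failing each criterion
    frac_low_coverage: float = 0.12
    frac_low_af: float = 0.10
    frac_non_cosmic: float = 0.15
    frac_common_popfreq: float = 0.08
    frac_population_snp: float = 27.0 / 71.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.n_drugs < 1:
            raise ConfigError("n_drugs must be >= 1")
        for name in ("probe_noise_sd", "response_noise_sd", "mutation_rate",
                     "well_noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("focal_amp_probability", "frac_low_coverage", "frac_low_af",
                     "frac_non_cosmic", "frac_common_popfreq", "frac_population_snp"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} out of [0, 1]")
        lo, hi = self.focal_amp_copy_range
        if not 0 < lo <= hi:
            raise ConfigError("focal_amp_copy_range must satisfy 0 < lo <= hi")
        panel_arms = {g.arm_name for g in self.panel}
        for ev in self.arm_event_rates:
            if ev.arm not in panel_arms:
                raise ConfigError(f"arm event on unknown arm: {ev.arm}")
        genes = {g.gene_id for g in self.panel}
        if self.focal_amp_gene not in genes:
            raise ConfigError(f"focal amplification gene not in panel: {self.focal_amp_gene}")
        for pp in self.planted_pairs:
            if pp.gene_id not in genes:
                raise ConfigError(f"planted pair references unknown gene: {pp.gene_id}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.panel]


def default_drug_library(panel: Sequence[GeneLocus], n_drugs: int = 418,
                         n_untargeted: int = 2) -> pd.DataFrame:
    """Deterministic bundled drug library.

    Columns: compound_id, name, mechanism_class, target_genes (semicolon
    separated). Every drug annotates one panel gene as its expected target
    except the last ``n_untargeted`` drugs (so the default 418-drug library
    yields 416 expected gene-drug pairs). Quiet (never-aberrant) genes are not
    used as targets, so every expected pair lies inside the screened universe.
    """
    genes = [g.gene_id for g in panel if g.gene_id not in set(QUIET_GENES)]
    rows = []
    for i in range(n_drugs):
        cid = f"D{i + 1:03d}"
        if i < len(_NAMED_COMPOUNDS):
            name, mech = _NAMED_COMPOUNDS[i]
        else:
            name = cid
            mech = DRUG_CLASSES[i % len(DRUG_CLASSES)]
        target = "" if i >= n_drugs - n_untargeted else genes[i % len(genes)]
        rows.append({"compound_id": cid, "name": name,
                     "mechanism_class": mech, "target_genes": target})
    return pd.DataFrame(rows)


def expected_pairs(library: pd.DataFrame) -> set[tuple[str, str]]:
    """(gene_id, drug_id) pairs annotated as expected targets in a library."""
    pairs: set[tuple[str, str]] = set()
    for row in library.itertuples(index=False):
        for gene in str(row.target_genes).split(";"):
            gene = gene.strip()
            if gene and gene.lower() != "nan":
                pairs.add((gene, row.compound_id))
    return pairs


@dataclass
class SyntheticTruth:
    """Planted events/effects and the implied null set."""

    arm_events: dict[str, tuple[tuple[str, str], ...]]  # sample -> ((arm, event), ...)
    true_copies: pd.DataFrame  # gene x sample
    planted_pairs: tuple[PlantedPair, ...]
    gene_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]

    @property
    def planted_set(self) -> set[tuple[str, str]]:
        return {(p.gene_id, p.drug_id) for p in self.planted_pairs}

    @property
    def n_pairs(self) -> int:
        return len(self.gene_ids) * len(self.drug_ids)

    @property
    def n_null_pairs(self) -> int:
        return self.n_pairs - len(self.planted_set)

    def null_pairs(self) -> Iterable[tuple[str, str]]:
        planted = self.planted_set
        return (
            p for p in itertools.product(self.gene_ids, self.drug_ids) if p not in planted
        )


@dataclass
class Cohort:
    """One generated cohort: raw data plus ground truth."""

    config: CohortConfig
    seed: int
    truth: SyntheticTruth
    probe_table: pd.DataFrame  # probe_id, gene_id, chrom, arm + sample columns
    plates: list[PlateReadings]
    latent_cytotoxicity: pd.DataFrame  # drug x sample, % (post-clip)
    variants: list[VariantRecord]
    drug_library: pd.DataFrame


def generate_copy_number(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[dict[str, tuple[tuple[str, str], ...]], pd.DataFrame, pd.DataFrame]:
    """Draw arm events and focal amplifications; emit true copies and probes.

    Baseline is diploid (2 copies). A sampled arm event shifts every non-quiet
    gene on that arm by +/-1 copy (clipped at 0); a focal amplification
    overrides the target gene's copies with a uniform draw from the configured
    range. Probe log2 ratio = log2(copies/2) + Normal(0, probe_noise_sd).
    """
    samples = config.sample_ids
    genes = config.gene_ids
    quiet = set(config.quiet_genes)
    arm_of = {g.gene_id: g.arm_name for g in config.panel}

    copies = pd.DataFrame(2.0, index=genes, columns=samples)
    arm_events: dict[str, tuple[tuple[str, str], ...]] = {s: () for s in samples}

    for ev in config.arm_event_rates:
        hit = rng.random(config.n_samples) < ev.probability
        members = [g for g in genes if arm_of[g] == ev.arm and g not in quiet]
        for s, h in zip(samples, hit):
            if h:
                arm_events[s] = arm_events[s] + ((ev.arm, ev.event),)
                copies.loc[members, s] += ev.shift
    copies = copies.clip(lower=0.0)

    amp_hit = rng.random(config.n_samples) < config.focal_amp_probability
    lo, hi = config.focal_amp_copy_range
    amp_draws = rng.uniform(lo, hi, size=config.n_samples)
    for s, h, c in zip(samples, amp_hit, amp_draws):
        if h:
            copies.loc[config.focal_amp_gene, s] = c

    rows = []
    for g in config.panel:
        base = np.log2(np.maximum(copies.loc[g.gene_id].to_numpy(), 1e-3) / 2.0)
        for pid in g.probe_ids:
            rows.append((pid, g.gene_id, g.chrom, g.arm, base))
    noise = rng.normal(0.0, config.probe_noise_sd, size=(len(rows), config.n_samples)) \
        if config.probe_noise_sd > 0 else np.zeros((len(rows), config.n_samples))
    probe_table = pd.DataFrame(
        {
            "probe_id": [r[0] for r in rows],
            "gene_id": [r[1] for r in rows],
            "chrom": [r[2] for r in rows],
            "arm": [r[3] for r in rows],
        }
    )
    values = np.vstack([r[4] for r in rows]) + noise
    for j, s in enumerate(samples):
        probe_table[s] = values[:, j]
    return arm_events, copies, probe_table


def generate_drug_response(
    true_copies: pd.DataFrame,
    drug_library: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[PlateReadings]]:
    """Latent per-drug cytotoxicity and the plate RLU readings that encode it.

    latent(d, s) = baseline(d) + sum over planted pairs on d of
    slope * (copies(g, s) - 2) + Normal(0, response_noise_sd), clipped to
    [-20, 100]. RLU = rlu_scale * (1 - latent/100) with multiplicative well
    noise; DMSO wells sit at rlu_scale and staurosporine wells near zero.
    """
    drug_ids = list(drug_library["compound_id"])
    known_drugs = set(drug_ids)
    for pp in config.planted_pairs:
        if pp.drug_id not in known_drugs:
            raise ConfigError(f"planted pair references unknown drug: {pp.drug_id}")

    samples = list(true_copies.columns)
    mu, sd = config.baseline_potency
    baseline = rng.normal(mu, sd, size=len(drug_ids)) if sd > 0 else np.full(len(drug_ids), mu)
    latent = np.tile(baseline[:, None], (1, len(samples)))

    d_index = {d: i for i, d in enumerate(drug_ids)}
    for pp in config.planted_pairs:
        dosage = true_copies.loc[pp.gene_id].to_numpy() - 2.0
        latent[d_index[pp.drug_id]] += pp.slope * dosage
    if config.response_noise_sd > 0:
        latent = latent + rng.normal(0.0, config.response_noise_sd, size=latent.shape)
    latent = np.clip(latent, -20.0, 100.0)
    latent_df = pd.DataFrame(latent, index=drug_ids, columns=samples)

    def noisy(base: np.ndarray) -> np.ndarray:
        if config.well_noise_cv > 0:
            base = base * (1.0 + rng.normal(0.0, config.well_noise_cv, size=base.shape))
        return np.maximum(base, 0.0)

    plates = []
    for s in samples:
        comp_ids: list[str] = []
        base_rlu: list[float] = []
        for d in drug_ids:
            rlu = config.rlu_scale * (1.0 - latent_df.at[d, s] / 100.0)
            comp_ids.extend([d] * config.n_replicate_wells)
            base_rlu.extend([rlu] * config.n_replicate_wells)
        comp_ids.extend([DMSO] * config.n_dmso_wells)
        base_rlu.extend([config.rlu_scale] * config.n_dmso_wells)
        comp_ids.extend([STAUROSPORINE] * config.n_stauro_wells)
        base_rlu.extend([config.rlu_scale * config.stauro_viability] * config.n_stauro_wells)
        rlu = noisy(np.asarray(base_rlu, dtype=float))
        wells = pd.DataFrame(
            {
                "well": [f"W{i + 1:04d}" for i in range(len(comp_ids))],
                "compound_id": comp_ids,
                "rlu": rlu,
            }
        )
        plates.append(PlateReadings(plate_id=f"P_{s}", sample_id=s, wells=wells))
    return latent_df, plates


_BASES = ("A", "C", "G", "T")


def generate_variants(config: CohortConfig, rng: np.random.Generator) -> list[VariantRecord]:
    """Sparse somatic variant candidates: Poisson(mutation_rate) per sample.

    Field values are drawn so a configurable fraction of records fails each
    downstream filter criterion, and a configurable fraction is flagged as a
    recurrent population SNP.
    """
    genes = config.gene_ids
    chrom_of = {g.gene_id: g.chrom for g in config.panel}
    gene_index = {g: i for i, g in enumerate(genes)}
    records: list[VariantRecord] = []
    for s in config.sample_ids:
        n = int(rng.poisson(config.mutation_rate))
        for _ in range(n):
            gene = genes[int(rng.integers(0, len(genes)))]
            if rng.random() < config.frac_low_coverage:
                coverage = int(rng.integers(20, 101))
            else:
                coverage = int(rng.integers(101, 1000))
            if rng.random() < config.frac_low_af:
                af = float(rng.uniform(0.01, 0.0999))
            else:
                af = float(rng.uniform(0.10, 0.90))
            cosmic = bool(rng.random() >= config.frac_non_cosmic)
            if rng.random() < config.frac_common_popfreq:
                popfreq = float(rng.uniform(0.01, 0.20))
            else:
                popfreq = float(rng.uniform(0.0, 0.0099))
            psnp = bool(rng.random() < config.frac_population_snp)
            pos = 1_000_000 + gene_index[gene] * 1_000 + int(rng.integers(0, 1_000))
            ref = _BASES[int(rng.integers(0, 4))]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            records.append(
                VariantRecord(
                    sample_id=s, gene_id=gene, chrom=chrom_of[gene], pos=pos,
                    ref=ref, alt=alt, coverage=coverage, allele_fraction=af,
                    cosmic_reported=cosmic, population_frequency=popfreq,
                    is_population_snp=psnp,
                )
            )
    return records


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Generate a full cohort from one root seed (deterministic)."""
    arm_events, copies, probe_table = generate_copy_number(
        config, child_rng(seed, "copy_number")
    )
    library = default_drug_library(config.panel, config.n_drugs)
    latent, plates = generate_drug_response(
        copies, library, config, child_rng(seed, "drug_response")
    )
    variants = generate_variants(config, child_rng(seed, "variants"))
    truth = SyntheticTruth(
        arm_events=arm_events,
        true_copies=copies,
        planted_pairs=config.planted_pairs,
        gene_ids=tuple(config.gene_ids),
        drug_ids=tuple(library["compound_id"]),
    )
    return Cohort(
        config=config, seed=seed, truth=truth, probe_table=probe_table,
        plates=plates, latent_cytotoxicity=latent, variants=variants,
        drug_library=library,
    )


def population_nonnull_pairs(config: CohortConfig) -> set[tuple[str, str]]:
    """All (gene, drug) pairs whose population correlation is nonzero.

    Arm events are all-or-none, so every non-quiet gene on a planted gene's
    arm carries *identical* copy-number variation and therefore the same
    population correlation with the planted drug as the planted gene itself.
    The true null set for false-discovery accounting is the complement of
    this expansion, not of the planted list alone.
    """
    arm_of = {g.gene_id: g.arm_name for g in config.panel}
    quiet = set(config.quiet_genes)
    mates: dict[str, list[str]] = {}
    for g in config.panel:
        if g.gene_id not in quiet:
            mates.setdefault(g.arm_name, []).append(g.gene_id)
    out: set[tuple[str, str]] = set()
    for pp in config.planted_pairs:
        for mate in mates.get(arm_of[pp.gene_id], [pp.gene_id]):
            out.add((mate, pp.drug_id))
    return out


def planted_pairs_for_target_r(
    config: CohortConfig,
    n_pairs: int,
    target_r: float = 0.95,
    rng: np.random.Generator | None = None,
    alternate_sign: bool = True,
) -> tuple[PlantedPair, ...]:
    """Choose planted pairs whose slope implies a target population |r|.

    For a gene on an arm with event probability p, copies across samples are
    2 +/- Bernoulli(p), so sd(copies) = sqrt(p(1-p)). With global response
    noise sigma, slope = sigma * (r / sqrt(1 - r^2)) / sd(copies) gives the
    requested population correlation between copies and latent cytotoxicity.
    Distinct drugs are used for every pair; the focal-amp gene is avoided.
    """
    if not 0 < target_r < 1:
        raise ConfigError("target_r must be in (0, 1)")
    if config.response_noise_sd <= 0:
        raise ConfigError("target-r planting requires response_noise_sd > 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    arm_p = {ev.arm: ev.probability for ev in config.arm_event_rates
             if 0 < ev.probability < 1}
    eligible = [
        g for g in config.panel
        if g.arm_name in arm_p
        and g.gene_id not in set(config.quiet_genes)
        and g.gene_id != config.focal_amp_gene
    ]
    if not eligible:
        raise ConfigError("no eligible genes on event-bearing arms to plant on")
    drug_ids = [f"D{i + 1:03d}" for i in range(config.n_drugs)]
    if n_pairs > len(drug_ids):
        raise ConfigError("more planted pairs than drugs")
    chosen_drugs = rng.choice(len(drug_ids), size=n_pairs, replace=False)
    k = target_r / np.sqrt(1.0 - target_r**2)
    pairs = []
    for i, di in enumerate(chosen_drugs):
        g = eligible[int(rng.integers(0, len(eligible)))]
        p = arm_p[g.arm_name]
        slope = config.response_noise_sd * k / np.sqrt(p * (1.0 - p))
        if alternate_sign and i % 2 == 1:
            slope = -slope
        pairs.append(PlantedPair(g.gene_id, drug_ids[int(di)], float(slope)))
    return tuple(pairs)


def with_planted_pairs(config: CohortConfig, pairs: Sequence[PlantedPair]) -> CohortConfig:
    """Copy of a config with the given planted pairs."""
    return replace(config, planted_pairs=tuple(pairs))
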
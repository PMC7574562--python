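"""Synthetic cfDNA epigenome-mixture generator.

Emulates the count structure of covalent-tagging CG sequencing (uTOP-seq for
unmodified CGs, hmTOP-seq for 5hmCGs) on a scaled-down genome:

* a CG-site catalog placed by a homogeneous Poisson process with 10x-dense
  CG-island clusters (density renormalised so the genome-wide mean CG rate
  equals the configured rate);
* per-tissue, per-site capture propensities: placental hypomethylation is
  planted as contiguous domains where the placenta uCG propensity is boosted;
  5hmCG propensities are sparse, tissue-discriminated and calibrated so the
  genome-wide placenta:maternal ratio matches the configured value (default
  0.021/0.012 from tissue-level mass-spectrometry measurements);
* cfDNA samples drawn as maternal/fetal mixtures: per-site expected rate
  (1-ff)*maternal + ff*fetal, with the fetal component of the target
  chromosome multiplied by 1.5 for trisomy-21, and read counts allocated by
  a single multinomial draw of the sample's depth over sites.

All randomness flows through one seeded ``numpy.random.Generator`` (PCG64);
a fixed seed yields a bit-identical cohort.

No sequence-level simulation is attempted (no FASTQ, no error model, no
fragment-length modelling of fetal-DNA shortness).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix, SiteIndex

#: number of CG sites in the human genome; human-genome-scale read depths are
#: rescaled by (synthetic CG count / this) so per-CG coverage density matches
HUMAN_CG_SITES = 28_000_000

ASSAYS = ("uCG", "5hmCG")
TISSUES = ("maternal_blood", "placenta")
GROUPS = ("NPC", "pregnant_healthy", "pregnant_T21", "CVS")

ANNOTATION_NAMES = (
    "CGI", "promoter", "5UTR", "exon", "intron", "3UTR", "enhancer",
    "lincRNA_promoter",
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    """Settings for the synthetic genome and tissue epigenomes.

    Defaults give 3 chromosomes x 2 Mb at 1 CG / 100 bp (~60k CG sites):
    a chr21 analog (the aneuploidy target) and two candidate reference
    chromosomes named after the references used for uCG and 5hmCG data.
    """

    chroms: tuple[tuple[str, int], ...] = (
        ("chr21a", 2_000_000), ("chr16a", 2_000_000), ("chr20a", 2_000_000),
    )
    cg_rate: float = 0.01                  # mean CG sites per bp, genome-wide
    cgi_fraction: float = 0.02             # fraction of genome inside CG islands
    cgi_length: int = 1_000                # bp per island
    cgi_density_boost: float = 10.0        # CG density multiplier inside CGIs
    hypo_domain_length: int = 100_000      # placental hypomethylated block, bp
    hypo_fraction: float = 0.2             # fraction of each chromosome covered
    placenta_hypo_boost: float = 6.0       # placenta uCG propensity x in domains
    cgi_capture_boost: float = 5.0         # uCG propensity x in CGIs (both tissues)
    promoter_capture_boost: float = 2.0    # uCG propensity x in promoters/5'UTRs
    hm_maternal_active: float = 0.10       # P(site carries maternal 5hmC)
    hm_placenta_active: float = 0.20       # P(site carries placental 5hmC)
    hm_exon_boost: float = 3.0             # 5hmC activity x in exons/3'UTRs
    hm_discrimination: float = 1.0         # P(placental 5hmC state independent)
    hm_ratio: float = 0.021 / 0.012        # genome-wide placenta:maternal 5hmC
    gene_spacing: int = 50_000             # one gene model per this many bp
    enhancer_spacing: int = 25_000
    linc_spacing: int = 100_000
    mqtl_per_mb: float = 90.0              # HM450-like probe density
    mqtl_fraction: float = 0.2             # fraction of probes flagged as mQTL
    target_chrom: str = "chr21a"

    def validate(self) -> None:
        if len(self.chroms) < 3:
            raise ValueError("need at least 3 chromosomes (target + 2 references)")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        for attr in ("cg_rate", "cgi_density_boost", "placenta_hypo_boost",
                     "hm_ratio"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if not 0 <= self.cgi_fraction < 1 / self.cgi_density_boost:
            raise ValueError("cgi_fraction * cgi_density_boost must stay below 1")
        if self.target_chrom not in [c[0] for c in self.chroms]:
            raise ValueError("target_chrom not among chromosomes")

    @property
    def expected_cg_sites(self) -> float:
        return self.cg_rate * sum(length for _, length in self.chroms)


@dataclass
class GenomeModel:
    """Synthetic genome: CG catalog, annotations and tissue propensities."""

    config: GenomeConfig
    sites: SiteIndex
    #: (assay, tissue) -> per-site non-negative capture weight
    propensity: dict[tuple[str, str], np.ndarray]
    #: annotation name -> chrom -> (k, 2) half-open intervals
    annotations: dict[str, dict[str, np.ndarray]]
    #: chrom -> (k, 2) planted hypomethylated placental domains
    hypo_domains: dict[str, np.ndarray]
    mqtl_probes: pd.DataFrame              # chrom, pos, is_mqtl

    @property
    def n_sites(self) -> int:
        return self.sites.n_sites

    @property
    def depth_scale(self) -> float:
        """Factor converting human-genome-scale read counts to this genome."""
        return self.n_sites / HUMAN_CG_SITES

    def scale_depth(self, human_reads: float) -> int:
        """Synthetic depth matching a human-genome-scale processed-read count."""
        return int(round(human_reads * self.depth_scale))


@dataclass
class SampleMeta:
    sample_id: str
    group: str
    assay: str
    fetal_sex: str                        # XX | XY | NA
    ff: float                             # reference fetal fraction in [0, 1]
    depth: int                            # intended processed-read count

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if not 0.0 <= self.ff <= 1.0:
            raise ValueError("ff must lie in [0, 1]")
        if (self.ff == 0.0) != (self.group == "NPC"):
            raise ValueError("ff == 0 iff group == NPC")
        if (self.ff == 1.0) != (self.group == "CVS"):
            raise ValueError("ff == 1 iff group == CVS")


@dataclass
class CohortTruth:
    """Ground truth written alongside a simulated cohort."""

    ff: dict[str, float]
    karyotype: dict[str, str]             # sample_id -> euploid | T21
    #: contrast name -> list of (chrom, window_start, effect_direction)
    planted_dmr_windows: dict[str, list[tuple[str, int, str]]]


@dataclass
class CohortConfig:
    """Group sizes, depths and effect settings for one simulated cohort."""

    assay: str = "uCG"
    n_npc: int = 7
    n_healthy: int = 8
    n_t21: int = 5
    n_cvs: int = 7
    ff_range: tuple[float, float] = (0.06, 0.10)
    t21_dosage: float = 1.5               # fetal target-chromosome copy ratio
    depth_human_reads: float = 10e6       # full library, human-genome scale
    overdispersion: float = 0.0           # gamma CV of per-site rate noise; 0 = off
    #: planted DMR study: (n windows, placenta propensity multiplier) or None
    planted_dmr: tuple[int, float] | None = None
    planted_dmr_width: int = 100
    contaminate_npc: int = 0              # first k NPCs drawn from placenta
    id_prefix: str = ""                   # sample-id prefix (merged cohorts)

    def validate(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        lo, hi = self.ff_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("pregnant ff range must lie strictly inside (0, 1)")
        if self.t21_dosage <= 0:
            raise ValueError("t21_dosage must be positive")
        if self.depth_human_reads <= 0:
            raise ValueError("depth must be positive")


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _lattice_intervals(
    rng: np.random.Generator, length: int, n: int, item_len: int, lattice: int
) -> np.ndarray:
    """n non-overlapping ``item_len`` intervals on a lattice within [0, length)."""
    n_slots = length // lattice
    if n > n_slots:
        raise ValueError("too many intervals requested for chromosome length")
    starts = np.sort(rng.choice(n_slots, size=n, replace=False)) * lattice
    return np.column_stack([starts, starts + item_len]).astype(np.int64)


def _in_intervals(pos: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask: does each position fall in any half-open interval?"""
    if intervals.size == 0:
        return np.zeros(pos.size, dtype=bool)
    starts, ends = intervals[:, 0], intervals[:, 1]
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(pos.size, dtype=bool)
    hit[ok] = pos[ok] < ends[idx[ok]]
    return hit


def _gene_annotations(
    rng: np.random.Generator, length: int, cfg: GenomeConfig
) -> dict[str, list[tuple[int, int]]]:
    """Toy gene models (promoter/UTRs/exons/introns), enhancers, lincRNA promoters."""
    out: dict[str, list[tuple[int, int]]] = {n: [] for n in ANNOTATION_NAMES if n != "CGI"}
    for g0 in range(2_000, length - 12_000, cfg.gene_spacing):
        g = g0 + int(rng.integers(0, min(5_000, cfg.gene_spacing // 4)))
        out["promoter"].append((max(0, g - 2_000), g))
        out["5UTR"].append((g, g + 200))
        out["exon"].append((g + 200, g + 400))
        out["intron"].append((g + 400, g + 3_000))
        out["exon"].append((g + 3_000, g + 3_200))
        out["intron"].append((g + 3_200, g + 8_000))
        out["exon"].append((g + 8_000, g + 9_500))
        out["3UTR"].append((g + 9_500, g + 10_000))
    for e0 in range(12_000, length - 1_000, cfg.enhancer_spacing):
        e = e0 + int(rng.integers(0, 2_000))
        out["enhancer"].append((e, e + 500))
    for l0 in range(30_000, length - 2_000, cfg.linc_spacing):
        loc = l0 + int(rng.integers(0, 2_000))
        out["lincRNA_promoter"].append((loc, loc + 1_000))
    return out


def build_genome(config: GenomeConfig, seed: int) -> GenomeModel:
    """Build a synthetic genome with tissue epigenome propensities.

    Deterministic for a fixed ``(config, seed)``. The realised CG count is
    checked to fall within 10% of the configured expectation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom_names = [c[0] for c in config.chroms]
    chrom_lengths = np.array([c[1] for c in config.chroms], dtype=np.int64)

    annotations: dict[str, dict[str, np.ndarray]] = {n: {} for n in ANNOTATION_NAMES}
    hypo_domains: dict[str, np.ndarray] = {}
    all_chrom_id, all_pos = [], []

    for cid, (name, length) in enumerate(config.chroms):
        # CG islands on a lattice (guarantees non-overlap)
        n_cgi = int(length * config.cgi_fraction / config.cgi_length)
        cgi = _lattice_intervals(rng, length, n_cgi, config.cgi_length,
                                 lattice=5 * config.cgi_length)
        annotations["CGI"][name] = cgi

        # density renormalised so the genome-wide mean rate equals cg_rate:
        # background runs at r_bg everywhere, CGIs add (r_cgi - r_bg) on top
        f = n_cgi * config.cgi_length / length
        r_bg = config.cg_rate * (1 - config.cgi_density_boost * f) / (1 - f)
        r_cgi = config.cg_rate * config.cgi_density_boost
        n_bg = rng.poisson(r_bg * length)
        pos_bg = rng.integers(0, length, size=n_bg)
        n_in = rng.poisson((r_cgi - r_bg) * f * length)
        if n_in > 0 and n_cgi > 0:
            which = rng.integers(0, n_cgi, size=n_in)
            pos_in = cgi[which, 0] + rng.integers(0, config.cgi_length, size=n_in)
        else:
            pos_in = np.empty(0, dtype=np.int64)
        pos = np.unique(np.concatenate([pos_bg, pos_in]).astype(np.int64))
        pos = pos[np.concatenate([[True], np.diff(pos) >= 2])]   # CGs cannot overlap
        all_chrom_id.append(np.full(pos.size, cid, dtype=np.int32))
        all_pos.append(pos)

        # planted hypomethylated placental domains, equal coverage per chromosome
        n_dom = int(length * config.hypo_fraction / config.hypo_domain_length)
        hypo_domains[name] = _lattice_intervals(
            rng, length, n_dom, config.hypo_domain_length,
            lattice=config.hypo_domain_length,
        )

        for aname, ivals in _gene_annotations(rng, length, config).items():
            annotations[aname][name] = np.array(ivals, dtype=np.int64).reshape(-1, 2)

    sites = SiteIndex(chrom_names, chrom_lengths,
                      np.concatenate(all_chrom_id), np.concatenate(all_pos))
    expected = config.expected_cg_sites
    if not 0.9 * expected <= sites.n_sites <= 1.1 * expected:
        raise RuntimeError(
            f"realised CG count {sites.n_sites} outside 10% of target {expected:.0f}"
        )

    # per-site annotation masks needed for the propensities
    sl = sites.slices()
    def site_mask(intervals_by_chrom: dict[str, np.ndarray]) -> np.ndarray:
        mask = np.zeros(sites.n_sites, dtype=bool)
        for chrom, s in sl.items():
            mask[s] = _in_intervals(sites.pos[s], intervals_by_chrom.get(chrom,
                                    np.empty((0, 2), dtype=np.int64)))
        return mask

    in_cgi = site_mask(annotations["CGI"])
    in_prom = site_mask(annotations["promoter"]) | site_mask(annotations["5UTR"])
    in_exonic = site_mask(annotations["exon"]) | site_mask(annotations["3UTR"])
    in_hypo = site_mask(hypo_domains)

    # uCG: beta base, capture boosts in CGIs/promoters shared by both tissues,
    # placental hypomethylation as a multiplicative domain boost
    base_u = rng.beta(2.0, 2.0, size=sites.n_sites)
    base_u *= np.where(in_cgi, config.cgi_capture_boost, 1.0)
    base_u *= np.where(in_prom, config.promoter_capture_boost, 1.0)
    ucg_maternal = base_u
    ucg_placenta = base_u * np.where(in_hypo, config.placenta_hypo_boost, 1.0)

    # 5hmCG: sparse activity, exon/3'UTR enriched; placenta redraws its
    # activity state independently with probability hm_discrimination, then
    # the whole vector is rescaled to the calibrated genome-wide ratio
    act_boost = np.where(in_exonic, config.hm_exon_boost, 1.0)
    p_m = np.clip(config.hm_maternal_active * act_boost, 0.0, 1.0)
    p_p = np.clip(config.hm_placenta_active * act_boost, 0.0, 1.0)
    m_active = rng.random(sites.n_sites) < p_m
    hm_maternal = np.where(m_active, rng.beta(2.0, 2.0, size=sites.n_sites), 0.0)
    redraw = rng.random(sites.n_sites) < config.hm_discrimination
    p_active = np.where(redraw, rng.random(sites.n_sites) < p_p, m_active)
    hm_placenta = np.where(
        p_active,
        np.where(redraw, rng.beta(2.0, 2.0, size=sites.n_sites), hm_maternal),
        0.0,
    )
    if hm_placenta.sum() <= 0:
        raise RuntimeError("degenerate genome: placental 5hmCG propensity is zero")
    hm_placenta *= config.hm_ratio * hm_maternal.sum() / hm_placenta.sum()

    n_probes = (sites.chrom_lengths / 1e6 * config.mqtl_per_mb).astype(int)
    probe_rows = []
    for cid, name in enumerate(chrom_names):
        ppos = np.sort(rng.integers(0, chrom_lengths[cid], size=n_probes[cid]))
        flags = rng.random(n_probes[cid]) < config.mqtl_fraction
        probe_rows.append(pd.DataFrame({"chrom": name, "pos": ppos, "is_mqtl": flags}))
    mqtl = pd.concat(probe_rows, ignore_index=True)

    return GenomeModel(
        config=config,
        sites=sites,
        propensity={
            ("uCG", "maternal_blood"): ucg_maternal,
            ("uCG", "placenta"): ucg_placenta,
            ("5hmCG", "maternal_blood"): hm_maternal,
            ("5hmCG", "placenta"): hm_placenta,
        },
        annotations=annotations,
        hypo_domains=hypo_domains,
        mqtl_probes=mqtl,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _plant_dmr_windows(
    genome: GenomeModel,
    placenta: np.ndarray,
    n_windows: int,
    boost: float,
    width: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    """Boost placental propensity in CGI-dense windows of the target chromosome."""
    target = genome.config.target_chrom
    s = genome.sites.slices()[target]
    pos = genome.sites.pos[s]
    in_cgi = _in_intervals(pos, genome.annotations["CGI"][target])
    wid = pos // width
    cgi_per_window = pd.Series(in_cgi).groupby(wid).sum()
    candidates = cgi_per_window.index[cgi_per_window >= 5].to_numpy()
    if candidates.size < n_windows:
        raise ValueError(
            f"only {candidates.size} CGI-dense windows available for planting"
        )
    chosen = rng.choice(candidates, size=n_windows, replace=False)
    chosen_set = np.isin(wid, chosen)
    out = placenta.copy()
    out[np.arange(s.start, s.stop)[chosen_set]] *= boost
    manifest = [(target, int(w * width), "+") for w in np.sort(chosen)]
    return out, manifest


def simulate_cohort(
    genome: GenomeModel,
    cohort_cfg: CohortConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[CoverageMatrix, list[SampleMeta], CohortTruth]:
    """Simulate a cfDNA/CV cohort with ground truth.

    Each sample's expected per-site rate is ``(1-ff)*maternal + ff*fetal``
    with the fetal target-chromosome component multiplied by the trisomy
    dosage for T21 samples; ``depth`` reads are then allocated over sites by
    one multinomial draw, so every sample's site counts sum to its depth.
    """
    cohort_cfg.validate()
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    assay = cohort_cfg.assay
    maternal = genome.propensity[(assay, "maternal_blood")]
    placenta = genome.propensity[(assay, "placenta")]

    planted: dict[str, list[tuple[str, int, str]]] = {}
    if cohort_cfg.planted_dmr is not None:
        n_w, boost = cohort_cfg.planted_dmr
        placenta, manifest = _plant_dmr_windows(
            genome, placenta, n_w, boost, cohort_cfg.planted_dmr_width, rng
        )
        planted["placenta_vs_maternal"] = manifest

    target_slice = genome.sites.slices()[genome.config.target_chrom]
    depth = genome.scale_depth(cohort_cfg.depth_human_reads)

    plan: list[tuple[str, str, float | None]] = []   # (group, karyotype, ff)
    for i in range(cohort_cfg.n_npc):
        plan.append(("NPC", "euploid", 0.0))
    for i in range(cohort_cfg.n_healthy):
        plan.append(("pregnant_healthy", "euploid", None))
    for i in range(cohort_cfg.n_t21):
        plan.append(("pregnant_T21", "T21", None))
    for i in range(cohort_cfg.n_cvs):
        plan.append(("CVS", "euploid", 1.0))

    counts = np.zeros((len(plan), genome.n_sites), dtype=np.int64)
    metas: list[SampleMeta] = []
    truth_ff: dict[str, float] = {}
    truth_kt: dict[str, str] = {}
    group_counter: dict[str, int] = {}
    lo, hi = cohort_cfg.ff_range
    n_contaminated = 0

    for row, (group, karyotype, ff_fixed) in enumerate(plan):
        k = group_counter.get(group, 0)
        group_counter[group] = k + 1
        sid = f"{cohort_cfg.id_prefix}{assay}_{group}_{k + 1:02d}"
        ff = float(rng.uniform(lo, hi)) if ff_fixed is None else ff_fixed
        if group == "NPC":
            sex = "NA"
        else:
            sex = "XY" if rng.random() < 0.5 else "XX"
        fetal = placenta
        if karyotype == "T21" and cohort_cfg.t21_dosage != 1.0:
            fetal = placenta.copy()
            fetal[target_slice] *= cohort_cfg.t21_dosage
        if group == "NPC" and n_contaminated < cohort_cfg.contaminate_npc:
            # wrong-tissue contamination: this plasma sample is placental
            rate = placenta.astype(float).copy()
            n_contaminated += 1
        else:
            rate = (1.0 - ff) * maternal + ff * fetal
        if cohort_cfg.overdispersion > 0:
            cv2 = cohort_cfg.overdispersion**2
            rate = rate * rng.gamma(1.0 / cv2, cv2, size=rate.size)
        total = rate.sum()
        if total <= 0:
            raise ValueError(f"degenerate genome: zero total propensity for {sid}")
        counts[row] = rng.multinomial(depth, rate / total)
        metas.append(SampleMeta(sid, group, assay, sex, ff, depth))
        truth_ff[sid] = ff
        truth_kt[sid] = karyotype

    matrix = CoverageMatrix(counts, [m.sample_id for m in metas], genome.sites)
    return matrix, metas, CohortTruth(truth_ff, truth_kt, planted)


def emit_read_starts(
    sample_counts: np.ndarray,
    genome: GenomeModel,
    jitter: int,
    seed: int | np.random.Generator,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Expand one sample's per-site counts into jittered read-start records.

    Every read start lies within ``jitter`` bp of its source CG (clipped to
    the chromosome); strand is drawn uniformly. With ``jitter <= 3`` the
    emitted reads remain assignable under the 3-bp counting rule.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample_counts = np.asarray(sample_counts, dtype=np.int64)
    if sample_counts.size != genome.n_sites:
        raise ValueError("counts vector does not match the genome's CG catalog")
    src = np.repeat(np.arange(genome.n_sites), sample_counts)
    pos = genome.sites.pos[src]
    if jitter > 0:
        pos = pos + rng.integers(-jitter, jitter + 1, size=pos.size)
    lengths = genome.sites.chrom_lengths[genome.sites.chrom_id[src]]
    pos = np.clip(pos, 0, lengths - 1)
    strand = np.where(rng.random(pos.size) < 0.5, "+", "-")
    chrom = np.asarray(genome.sites.chrom_names)[genome.sites.chrom_id[src]]
    return pd.DataFrame(
        {"chrom": chrom, "start": pos, "strand": strand, "sample_id": sample_id}
    )


# ---------------------------------------------------------------------------
# study conditions (reference study cohorts)
# ---------------------------------------------------------------------------

def ucg_study_genome_config() -> GenomeConfig:
    """uTOP-seq study genome: 3 x 20 Mb, ~600k CG sites.

    Sized so chromosome-ratio sampling noise at the 3M-read-equivalent depth
    sits well below the trisomy effect at the lowest study fetal fraction
    (see docs/methods.md for the power calculation).
    """
    return GenomeConfig(
        chroms=(("chr21a", 20_000_000), ("chr16a", 20_000_000),
                ("chr20a", 20_000_000)),
    )


def hm_study_genome_config() -> GenomeConfig:
    """hmTOP-seq study genome: 3 x 80 Mb, ~2.4M CG sites.

    Larger than the uCG genome because the 1M-read-equivalent depth claim
    is three times shallower and the 5hmC placental enrichment is capped by
    the mass-spectrometry calibration ratio 1.75.
    """
    return GenomeConfig(
        chroms=(("chr21a", 80_000_000), ("chr16a", 80_000_000),
                ("chr20a", 80_000_000)),
    )


def ucg_study_cohort_config() -> CohortConfig:
    """uCG cohort: 7 NPC / 8 healthy / 5 T21 / 7 CVS, ff ~ U(0.06, 0.10)."""
    return CohortConfig(assay="uCG", n_npc=7, n_healthy=8, n_t21=5, n_cvs=7)


def hm_study_cohort_config() -> CohortConfig:
    """5hmCG cohort: 7 NPC / 7 healthy / 4 T21 / 3 CVS, ff ~ U(0.06, 0.10)."""
    return CohortConfig(assay="5hmCG", n_npc=7, n_healthy=7, n_t21=4, n_cvs=3)


def simulate_study(
    assay: str, seed: int
) -> tuple[GenomeModel, CoverageMatrix, list[SampleMeta], CohortTruth]:
    """Simulate the default reference study cohort for one assay."""
    ss = np.random.SeedSequence(seed)
    genome_seed, cohort_ss = ss.spawn(2)
    if assay == "uCG":
        genome = build_genome(ucg_study_genome_config(),
                              int(genome_seed.generate_state(1)[0] % 2**31))
        cfg = ucg_study_cohort_config()
    elif assay == "5hmCG":
        genome = build_genome(hm_study_genome_config(),
                              int(genome_seed.generate_state(1)[0] % 2**31))
        cfg = hm_study_cohort_config()
    else:
        raise ValueError(f"unknown assay {assay!r}")
    matrix, meta, truth = simulate_cohort(genome, cfg, cohort_ss)
    return genome, matrix, meta, truth
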
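"""Synthetic structured wheat-landrace collections.

The generators emulate the statistical structure of a Mediterranean
landrace panel: ~153 accessions in three geographic subpopulations with
admixture, ~10^4 biallelic SNPs on the 21 bread-wheat chromosomes, a
consensus genetic map with physical positions, heritable phenology traits
scored in an augmented field design with replicated checks, country-level
climate covariates correlated with subpopulation, and a gene annotation
with stress/control expression values.

Subpopulation allele frequencies follow the Balding-Nichols construction:
an ancestral frequency p ~ Uniform(0.1, 0.9) per marker and subpopulation
frequencies Beta(p(1-F)/F, (1-p)(1-F)/F), so that the expected Wright
fixation index among subpopulations equals the ``fst`` parameter.
Admixed accessions draw each marker from a 50/50 mixture of two
subpopulation frequency vectors, reproducing the central cloud seen in
principal-coordinate plots of real panels.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, WHEAT_CHROMOSOMES, make_marker_map
from .datasets import CLIMATE_PERIODS, CLIMATE_VARIABLES

# Country pools per subpopulation: west, north and east Mediterranean
# (23 countries over three subpopulations, as in the real panel).
DEFAULT_COUNTRY_POOLS: dict[str, list[str]] = {
    "SP1": ["Spain", "Portugal", "France", "Morocco", "Algeria", "Tunisia", "Libya"],
    "SP2": ["Italy", "Croatia", "Bosnia & Herzegovina", "Serbia", "Macedonia",
            "Albania", "Bulgaria", "Romania"],
    "SP3": ["Greece", "Turkey", "Cyprus", "Syria", "Lebanon", "Israel", "Jordan",
            "Egypt"],
}

EXPRESSION_TISSUES = ["root", "shoot/leaf", "spike", "grain"]
EXPRESSION_STUDIES = ["drought_heat_seedlings", "spike_water_stress", "peg_seedlings"]

_GENE_FAMILIES = [
    "receptor-like kinase", "F-box protein", "disease resistance protein",
    "ethylene-responsive transcription factor", "ras-like GTP binding protein",
    "ATP-dependent chaperone ClpB", "cytochrome c oxidase subunit",
    "NADH-ubiquinone oxidoreductase", "unknown function",
]


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """World description for :func:`simulate_population`.

    fst is the divergence among subpopulations (Balding-Nichols F);
    admix_fraction the share of accessions drawn as two-subpopulation
    mixtures.  ``ld_scale_cm`` switches on an autoregressive haplotype
    mode in which allele states are correlated along the chromosome with
    correlation exp(-d/ld_scale_cm) at map distance d; by default markers
    are independent.
    """

    n_accessions: int = 153
    n_markers: int = 10458
    n_chromosomes: int = 21
    map_length_cm: float = 150.0
    bp_per_cm: float = 5.0e6
    n_subpops: int = 3
    fst: float = 0.10
    admix_fraction: float = 0.20
    missing_rate: float = 0.0
    ld_scale_cm: float | None = None
    country_pools: dict[str, list[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise InvalidConfigError("n_subpops must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise InvalidConfigError("fst must lie in [0, 1)")
        if not 0.0 <= self.admix_fraction <= 1.0:
            raise InvalidConfigError("admix_fraction must lie in [0, 1]")
        if self.n_markers < self.n_chromosomes:
            raise InvalidConfigError("need at least one marker per chromosome")
        if self.n_chromosomes < 1 or self.n_chromosomes > len(WHEAT_CHROMOSOMES):
            raise InvalidConfigError(
                f"n_chromosomes must be in [1, {len(WHEAT_CHROMOSOMES)}]")

    @property
    def chromosomes(self) -> list[str]:
        return WHEAT_CHROMOSOMES[: self.n_chromosomes]

    @property
    def subpop_labels(self) -> list[str]:
        return [f"SP{i + 1}" for i in range(self.n_subpops)]


@dataclass
class PlantedEffect:
    """Ground-truth additive QTL for parameter-recovery experiments.

    Either ``effect_size`` (trait units per alternate-allele copy) is
    taken literally, or, when ``heritability_share`` is given, the effect
    is rescaled so the marker explains exactly that fraction of the
    phenotypic variance.
    """

    marker_id: str
    trait_name: str = "trait"
    effect_size: float = 1.0
    heritability_share: float | None = None


def _subpop_frequencies(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """(n_subpops, n_markers) allele frequencies under Balding-Nichols."""
    p = rng.uniform(0.1, 0.9, size=cfg.n_markers)
    if cfg.fst == 0.0:
        return np.tile(p, (cfg.n_subpops, 1))
    a = p * (1.0 - cfg.fst) / cfg.fst
    b = (1.0 - p) * (1.0 - cfg.fst) / cfg.fst
    freqs = rng.beta(a, b, size=(cfg.n_subpops, cfg.n_markers))
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def _build_map(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    per = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per[: cfg.n_markers % cfg.n_chromosomes] += 1
    markers, chroms, cms, bps = [], [], [], []
    L = cfg.map_length_cm
    # wheat-like recombination landscape: the distal 30% of the genetic map
    # on each arm is recombination-rich (few Mb per cM), the central 40%
    # pericentromeric and physically expanded; rates average bp_per_cm.
    distal_rate = 0.3 * cfg.bp_per_cm
    central_rate = (1.0 - 2 * 0.3 * 0.3) / 0.4 * cfg.bp_per_cm

    def phys(cm: np.ndarray) -> np.ndarray:
        a, b = 0.3 * L, 0.7 * L
        out = np.where(cm <= a, cm * distal_rate,
                       np.where(cm <= b,
                                a * distal_rate + (cm - a) * central_rate,
                                a * distal_rate + 0.4 * L * central_rate
                                + (cm - b) * distal_rate))
        return out

    for chrom, k in zip(cfg.chromosomes, per):
        cm = np.sort(rng.uniform(0.0, L, size=k))
        # enforce strictly increasing positions
        cm = np.maximum.accumulate(cm + np.arange(k) * 1e-6)
        bp = np.round(phys(cm)).astype(np.int64) + 1
        bp = np.maximum.accumulate(bp + np.arange(k))
        markers += [f"M{chrom}_{i + 1}" for i in range(k)]
        chroms += [chrom] * k
        cms += list(cm)
        bps += list(bp)
    return make_marker_map(markers, chroms, cms, bps)


def _draw_genotypes(rng: np.random.Generator, freqs: np.ndarray,
                    marker_map: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    """Genotypes (n_markers,) for one accession with frequency vector freqs."""
    if cfg.ld_scale_cm is None:
        return rng.binomial(2, freqs)
    # Gaussian-copula haplotypes: latent AR(1) along each chromosome with
    # correlation exp(-d/ld_scale_cm); allele = latent below the quantile.
    from scipy.stats import norm

    thresh = norm.ppf(freqs)
    geno = np.zeros(len(freqs), dtype=np.int8)
    cm = marker_map["cm"].to_numpy()
    chrom = marker_map["chrom"].to_numpy()
    for _hap in range(2):
        z = np.empty(len(freqs))
        start = 0
        for c in pd.unique(chrom):
            sel = np.where(chrom == c)[0]
            d = np.diff(cm[sel])
            rho = np.exp(-d / cfg.ld_scale_cm)
            zc = np.empty(len(sel))
            zc[0] = rng.standard_normal()
            noise = rng.standard_normal(len(sel) - 1)
            for i, r in enumerate(rho):
                zc[i + 1] = r * zc[i] + math.sqrt(1.0 - r * r) * noise[i]
            z[sel] = zc
            start += len(sel)
        geno += (z < thresh).astype(np.int8)
    return geno


def simulate_population(cfg: SimConfig):
    """Generate (GenotypeMatrix, AccessionMeta, MarkerMap).

    AccessionMeta is a frame (accession_id, subpop, country, admixed,
    admix_parents); admixed accessions carry the label of their first
    mixture component.  Map positions are strictly increasing within each
    chromosome in both cM and bp.
    """
    rng = np.random.default_rng(cfg.seed)
    marker_map = _build_map(rng, cfg)
    freqs = _subpop_frequencies(rng, cfg)

    pools = cfg.country_pools or {
        sp: DEFAULT_COUNTRY_POOLS.get(sp, [f"{sp}_country{i}" for i in range(1, 8)])
        for sp in cfg.subpop_labels
    }

    n = cfg.n_accessions
    n_admixed = int(round(cfg.admix_fraction * n))
    assignment = rng.integers(0, cfg.n_subpops, size=n)
    admixed_idx = rng.choice(n, size=n_admixed, replace=False) if n_admixed else np.array([], int)
    is_admixed = np.zeros(n, dtype=bool)
    is_admixed[admixed_idx] = True

    calls = np.empty((n, cfg.n_markers), dtype=np.int8)
    meta_rows = []
    for i in range(n):
        sp_a = int(assignment[i])
        if is_admixed[i] and cfg.n_subpops > 1:
            others = [s for s in range(cfg.n_subpops) if s != sp_a]
            sp_b = int(rng.choice(others))
            f = 0.5 * (freqs[sp_a] + freqs[sp_b])
            parents = f"{cfg.subpop_labels[sp_a]}+{cfg.subpop_labels[sp_b]}"
        else:
            f = freqs[sp_a]
            parents = ""
        calls[i] = _draw_genotypes(rng, f, marker_map, cfg)
        label = cfg.subpop_labels[sp_a]
        country = str(rng.choice(pools[label]))
        meta_rows.append((f"acc{i + 1:03d}", label, country, bool(is_admixed[i]), parents))

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    letters = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=cfg.n_markers)
    alt_i = (ref_i + rng.integers(1, 4, size=cfg.n_markers)) % 4
    alleles = [(letters[r], letters[a]) for r, a in zip(ref_i, alt_i)]

    meta = pd.DataFrame(
        meta_rows, columns=["accession_id", "subpop", "country", "admixed", "admix_parents"])
    G = GenotypeMatrix(
        accession_ids=list(meta["accession_id"]),
        marker_ids=list(marker_map["marker"]),
        calls=calls,
        alleles=alleles,
    )
    return G, meta, marker_map


# ---------------------------------------------------------------------------
# phenology

def _genetic_scores(G: GenotypeMatrix, effects: Sequence[PlantedEffect],
                    sigma_p: float) -> np.ndarray:
    """Additive genetic score per accession; heritability-share effects are
    rescaled against the empirical marker variance so each explains its
    stated fraction of sigma_p^2."""
    score = np.zeros(G.n_accessions)
    x_all = G.dosage()
    mk_index = {m: j for j, m in enumerate(G.marker_ids)}
    total_share = 0.0
    for eff in effects:
        if eff.marker_id not in mk_index:
            raise InvalidConfigError(f"planted marker {eff.marker_id!r} not in matrix")
        x = x_all[:, mk_index[eff.marker_id]]
        beta = eff.effect_size
        if eff.heritability_share is not None:
            total_share += eff.heritability_share
            v = x.var()
            if v <= 0:
                raise InvalidConfigError(
                    f"planted marker {eff.marker_id!r} is monomorphic")
            beta = math.copysign(
                math.sqrt(eff.heritability_share * sigma_p**2 / v), eff.effect_size)
        score += beta * (x - x.mean())
    if total_share > 1.0 + 1e-12:
        raise InvalidConfigError("heritability shares per trait sum to > 1")
    return score


def simulate_phenology(
    G: GenotypeMatrix,
    effects: Sequence[PlantedEffect] = (),
    h2: float = 0.6,
    years: int = 3,
    field_layout: tuple[int, int] | None = None,
    seed: int = 0,
    trait_name: str = "D65",
    sigma_p: float = 5.0,
    n_background: int = 100,
    year_sd: float = 5.0,
    row_sd: float = 1.0,
    col_sd: float = 1.0,
    check_names: tuple[str, str] = ("check_1", "check_2"),
    check_ratio: int = 5,
) -> pd.DataFrame:
    """Field-plot records from a non-replicated augmented design.

    One plot per accession per year plus replicated check plots at a
    1:``check_ratio`` ratio.  The plot value is
    genetic score + year effect + row effect + column effect + residual,
    with the residual scaled so the planted-genetics share of
    (genetic + residual) variance equals ``h2``.  When the planted
    effects' heritability shares sum to less than ``h2``, the difference
    is filled by a polygenic background spread over ``n_background``
    randomly chosen markers, so structured panels yield
    structure-correlated traits even without major planted QTLs.

    Returns a long frame (year, row, col, genotype_id, is_check, trait,
    value).
    """
    if not 0.0 < h2 <= 1.0:
        raise InvalidConfigError("h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    planted_share = sum(e.heritability_share or 0.0 for e in effects)
    score = _genetic_scores(G, effects, sigma_p)
    background_share = 0.0
    if effects and all(e.heritability_share is not None for e in effects):
        background_share = max(h2 - planted_share, 0.0)
    elif not effects:
        background_share = h2
    if background_share > 0 and n_background > 0:
        # background polygene never reuses the planted QTL markers, so the
        # planted variance shares stay as stated
        planted = {e.marker_id for e in effects}
        pool = np.array([j for j, m in enumerate(G.marker_ids) if m not in planted])
        bg_idx = rng.choice(pool, size=min(n_background, len(pool)), replace=False)
        x = G.dosage()[:, bg_idx]
        w = rng.standard_normal(len(bg_idx))
        bg = (x - x.mean(axis=0)) @ w
        if bg.std() > 0:
            bg *= math.sqrt(background_share) * sigma_p / bg.std()
        score = score + bg

    var_g = score.var()
    if h2 < 1.0 and var_g > 0:
        resid_sd = math.sqrt(var_g * (1.0 - h2) / h2)
    elif h2 < 1.0:
        resid_sd = math.sqrt(1.0 - h2) * sigma_p
    else:
        resid_sd = 0.0

    n = G.n_accessions
    n_checks = max(n // check_ratio, 2)
    n_plots = n + n_checks
    if field_layout is None:
        n_cols = int(math.ceil(math.sqrt(n_plots)))
        n_rows = int(math.ceil(n_plots / n_cols))
        field_layout = (n_rows, n_cols)
    n_rows, n_cols = field_layout
    if n_rows * n_cols < n_plots:
        raise InvalidConfigError(
            f"layout {field_layout} too small for {n} accessions + {n_checks} checks")

    check_score = {name: 0.0 for name in check_names}
    records = []
    for year_i in range(years):
        year = 2016 + year_i
        year_eff = rng.normal(0.0, year_sd)
        row_eff = rng.normal(0.0, row_sd, size=n_rows)
        col_eff = rng.normal(0.0, col_sd, size=n_cols)
        # interleave checks every (check_ratio + 1)-th plot
        entries: list[tuple[str, bool, float]] = []
        acc_iter = iter(range(n))
        ci = 0
        placed = 0
        while placed < n_plots:
            if (placed % (check_ratio + 1)) == check_ratio and ci < n_checks:
                name = check_names[ci % len(check_names)]
                entries.append((name, True, check_score[name]))
                ci += 1
            else:
                try:
                    i = next(acc_iter)
                except StopIteration:
                    name = check_names[ci % len(check_names)]
                    entries.append((name, True, check_score[name]))
                    ci += 1
                    placed += 1
                    continue
                entries.append((G.accession_ids[i], False, score[i]))
            placed += 1
        perm = rng.permutation(n_plots)
        for plot, (gid, is_check, g) in zip(perm, entries):
            r, c = divmod(int(plot), n_cols)
            value = g + year_eff + row_eff[r] + col_eff[c] + rng.normal(0.0, resid_sd)
            records.append((year, r + 1, c + 1, gid, is_check, trait_name, value))
    return pd.DataFrame(
        records, columns=["year", "row", "col", "genotype_id", "is_check", "trait", "value"])


# ---------------------------------------------------------------------------
# climate

def default_sp_means(subpops: Sequence[str]) -> pd.DataFrame:
    """A plausible subpopulation x variable x period mean table: a smooth
    west-to-east gradient of warming/drying, roughly matching the spread
    of the packaged country normals."""
    base = {
        "Tmax": (12.0, 3.0), "Tmin": (3.0, 3.0), "Tmean": (7.5, 3.0),
        "Rh": (78.0, -4.0), "Sunshine": (3.0, 1.2), "Rad": (7.0, 2.5),
        "ET0": (150.0, 60.0), "Rain": (400.0, -120.0),
    }
    am_shift = {
        "Tmax": 11.0, "Tmin": 8.0, "Tmean": 9.5, "Rh": -10.0,
        "Sunshine": 4.0, "Rad": 11.0, "ET0": 180.0, "Rain": -250.0,
    }
    rows = []
    for k, sp in enumerate(subpops):
        for var in CLIMATE_VARIABLES:
            mu, slope = base[var]
            for period in CLIMATE_PERIODS:
                v = mu + slope * k + (am_shift[var] if period == "AM" else 0.0)
                if var in ("Rain", "ET0", "Rh"):
                    v = max(v, 0.0)
                rows.append((sp, var, period, v))
    return pd.DataFrame(rows, columns=["subpop", "variable", "period", "value"])


def simulate_climate(meta: pd.DataFrame, sp_means: pd.DataFrame | None = None,
                     country_noise_sd: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Country x variable x period climate values correlated with subpopulation.

    Every country inherits its subpopulation's mean per (variable, period)
    plus a country-level Gaussian perturbation of ``country_noise_sd``
    standard deviations scaled by the variable's across-subpopulation
    spread (so one unit of noise means one 'subpopulation step').
    """
    subpops = sorted(meta["subpop"].unique())
    if sp_means is None:
        sp_means = default_sp_means(subpops)
    bad = set(sp_means["period"]) - set(CLIMATE_PERIODS)
    if bad:
        raise ValueError(f"unknown period labels {sorted(bad)}; expected {CLIMATE_PERIODS}")
    rng = np.random.default_rng(seed)
    country_sp = meta.drop_duplicates("country").set_index("country")["subpop"]
    lookup = sp_means.set_index(["subpop", "variable", "period"])["value"]
    scale = sp_means.groupby(["variable", "period"])["value"].std().fillna(1.0)
    rows = []
    for country, sp in country_sp.items():
        for var in sp_means["variable"].unique():
            for period in sp_means[sp_means["variable"] == var]["period"].unique():
                mu = float(lookup.loc[(sp, var, period)])
                sd = float(scale.loc[(var, period)]) or 1.0
                rows.append((country, var, period,
                             mu + country_noise_sd * sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["country", "variable", "period", "value"])


# ---------------------------------------------------------------------------
# annotation + expression

def simulate_annotation_expression(
    marker_map: pd.DataFrame,
    n_genes: int = 500,
    stress_up_fraction: float = 0.1,
    delta_tpm_range: tuple[float, float] = (3.0, 8.0),
    seed: int = 0,
    gene_length_bp: tuple[int, int] = (2000, 8000),
):
    """Gene models on the simulated chromosomes plus a tpm expression table.

    A ``stress_up_fraction`` share of genes is planted as upregulated:
    in one random tissue their stress tpm exceeds control by a delta drawn
    from ``delta_tpm_range`` (whose lower bound should exceed the 2-tpm
    candidate filter).  All other gene x tissue deltas are small
    (|delta| <= 1).  Returns (annotation frame, expression frame).
    """
    if n_genes <= 0:
        raise InvalidConfigError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    chrom_extent = marker_map.groupby("chrom")["bp"].max()
    chroms = rng.choice(chrom_extent.index.to_numpy(), size=n_genes)
    ann_rows = []
    for i, chrom in enumerate(chroms):
        start = int(rng.integers(1, max(int(chrom_extent[chrom]) - gene_length_bp[1], 2)))
        end = start + int(rng.integers(*gene_length_bp))
        family = str(rng.choice(_GENE_FAMILIES))
        ann_rows.append((f"GENE{i + 1:05d}", str(chrom), start, end, family, ""))
    ann = pd.DataFrame(
        ann_rows, columns=["gene_id", "chrom", "start", "end", "family", "go_terms"])
    ann = ann.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    n_up = int(round(stress_up_fraction * n_genes))
    up_genes = rng.choice(ann["gene_id"].to_numpy(), size=n_up, replace=False)
    up_tissue = {g: EXPRESSION_TISSUES[int(rng.integers(0, len(EXPRESSION_TISSUES)))]
                 for g in up_genes}
    expr_rows = []
    for g in ann["gene_id"]:
        study = EXPRESSION_STUDIES[int(rng.integers(0, len(EXPRESSION_STUDIES)))]
        for tissue in EXPRESSION_TISSUES:
            control = float(rng.uniform(0.5, 10.0))
            if g in up_tissue and up_tissue[g] == tissue:
                delta = float(rng.uniform(*delta_tpm_range))
            else:
                delta = float(rng.uniform(-1.0, 1.0))
            stress = max(control + delta, 0.0)
            expr_rows.append((g, tissue, "control", study, control))
            expr_rows.append((g, tissue, "stress", study, stress))
    expr = pd.DataFrame(
        expr_rows, columns=["gene_id", "tissue", "condition", "study", "tpm"])
    return ann, expr
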
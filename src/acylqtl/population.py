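"""Synthetic F2 mapping populations: genotypes and anthocyanin phenotypes.

The generator emulates the statistical structure of an inbred x near-inbred
maize F2 cross genotyped at GBS density (post-imputation matrix):

* ~8,062 biallelic-coded SNPs on 10 chromosomes, denser near chromosome ends;
* meiosis under the Haldane (no-interference) model -- Poisson crossover
  counts with mean equal to the chromosome map length in Morgans, crossover
  positions uniform on the genetic map;
* 1:2:1 genotype segregation at every marker;
* residual heterozygosity in the mutant-stock founder, producing occasional
  third alleles at a site;
* optional missing-data and heterozygote-miscall degradation;
* phenotypes with the cross's effect structure: a monogenic recessive
  reduced-acylation trait, a bimodal acylation percentage (class means
  ~70.8% wild type vs ~15.0% mutant), and right-skewed anthocyanin content
  driven by four loci (+105.4 / -23.3 / -24.2 / -29.1 mg/kg shifts), with
  two HPLC replicates at ~3% CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .genome import B73V3_CHROM_LENGTHS, DEFAULT_CM_PER_MB, MarkerMap
from .genotypes import GenotypeMatrix, code_numeric
from .phenotypes import ACYLATED, COMPOUNDS, NON_ACYLATED
from .util import stage_rng


@dataclass(frozen=True)
class CausalLocus:
    """A trait-controlling locus placed on the genome (not necessarily at a marker).

    ``effects`` maps trait name -> additive shift in trait units, applied when
    the mode condition holds (recessive: homozygous for the recessive allele;
    dominant: at least one copy).  ``recessive_founder`` says which founder
    carries the recessive allele (0 = reference-line founder, 1 = mutant-stock
    founder).  Exactly one locus in a set is flagged ``is_acylation_locus``:
    its recessive class is the reduced-acylation (mutant) class.
    """

    name: str
    chromosome: int
    position: int
    mode: str = "recessive"
    effects: dict[str, float] = field(default_factory=dict)
    recessive_founder: int = 1
    is_acylation_locus: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("recessive", "dominant"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.recessive_founder not in (0, 1):
            raise InvalidConfigError("recessive_founder must be 0 or 1")

    def condition(self, recessive_dosage: np.ndarray) -> np.ndarray:
        """Boolean mask where the locus expresses its effect."""
        if self.mode == "recessive":
            return recessive_dosage == 2
        return recessive_dosage >= 1


def default_causal_loci() -> list[CausalLocus]:
    """The four AC-altering loci of the cross plus the inert pericarp-color locus.

    The reduced-acylation locus sits at chr1:300,173,138 (the candidate
    acyltransferase position).  The intensifier, colored-aleurone and
    colorless-aleurone regulators default to mid-arm positions on
    chromosomes 7, 9 and 10.
    """
    return [
        CausalLocus(
            "aat1", 1, 300_173_138,
            effects={"AC": -23.3}, recessive_founder=1, is_acylation_locus=True,
        ),
        CausalLocus("in1", 7, 88_000_000, effects={"AC": 105.4}, recessive_founder=1),
        CausalLocus("c1", 9, 78_500_000, effects={"AC": -29.1}, recessive_founder=0),
        CausalLocus("r1", 10, 74_800_000, effects={"AC": -24.2}, recessive_founder=0),
        CausalLocus("p1", 1, 48_000_000, effects={}, recessive_founder=1),
    ]


@dataclass(frozen=True)
class PopulationConfig:
    """All knobs of the synthetic population.

    Defaults are the study conditions of the cross: 128 genotyped F2
    individuals, 8,062 markers, wild-type acylation 70.8% vs mutant 15.0%,
    replicate CV 3.09%.  The AC baseline of 89.0 mg/kg puts the expected
    population mean at ~96.2 mg/kg once the four locus effects (each
    expressed in 1/4 of an F2) are added.
    """

    n_individuals: int = 128
    n_markers: int = 8062
    missing_rate: float = 0.0
    het_miscall_rate: float = 0.0
    residual_founder_het: float = 0.05
    seed: int = 1
    end_fraction: float = 0.2
    end_density_boost: float = 3.0
    cm_per_mb: float = DEFAULT_CM_PER_MB
    chrom_lengths: dict[int, int] = field(
        default_factory=lambda: dict(B73V3_CHROM_LENGTHS)
    )
    # trait parameters
    acylation_wt_mean: float = 70.8
    acylation_mut_mean: float = 15.0
    acylation_sd: float = 5.0
    ac_baseline: float = 89.0
    ac_noise_sigma: float = 0.35
    replicate_cv_pct: float = 3.09
    standard_total_area: float = 1.0e6
    standard_ac: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "het_miscall_rate", "residual_founder_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.n_individuals < 1 or self.n_markers < 1:
            raise InvalidConfigError("n_individuals and n_markers must be >= 1")
        if min(self.chrom_lengths.values(), default=1) <= 0:
            raise InvalidConfigError("chromosome lengths must be positive")
        if self.acylation_wt_mean < 0 or self.acylation_mut_mean < 0:
            raise InvalidConfigError("acylation class means must be non-negative")
        if self.ac_baseline < 0:
            raise InvalidConfigError("AC baseline must be non-negative")


@dataclass
class PhenotypeTable:
    """Generated phenotypes: replicate-level peaks plus per-sample truth.

    ``peaks`` has one row per sample-replicate with one column per compound;
    ``table`` has one row per sample with generated trait values, marker-gene
    scores, and causal truth indicators.
    """

    peaks: pd.DataFrame
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

def _allocate(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items, at least one per bin."""
    k = len(weights)
    if n < k:
        raise InvalidConfigError(f"need at least {k} markers (one per chromosome)")
    base = np.ones(k, dtype=int)
    rest = n - k
    quota = rest * weights / weights.sum()
    counts = base + np.floor(quota).astype(int)
    rem = quota - np.floor(quota)
    short = n - counts.sum()
    for i in np.argsort(-rem)[:short]:
        counts[i] += 1
    return counts


def build_marker_map(config: PopulationConfig) -> MarkerMap:
    """Place markers on 10 chromosomes with elevated density near the ends.

    Marker counts per chromosome are proportional to physical length (at
    least one per chromosome); within a chromosome, positions are sampled
    from a piecewise-uniform density whose terminal regions (a total
    ``end_fraction`` of the length, split between the two ends) have
    ``end_density_boost``-fold elevated density.
    """
    rng = stage_rng(config.seed, "marker_map")
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    counts = _allocate(config.n_markers, lengths)

    rows = []
    for chrom, length, m in zip(chroms, lengths, counts):
        half_end = config.end_fraction / 2.0
        # region weights: [0, h], [h, 1-h], [1-h, 1] with boosted ends
        w = np.array(
            [half_end * config.end_density_boost,
             1.0 - 2 * half_end,
             half_end * config.end_density_boost]
        )
        w = w / w.sum()
        pos: np.ndarray = np.empty(0, dtype=np.int64)
        while len(pos) < m:
            need = m - len(pos)
            region = rng.choice(3, size=need, p=w)
            u = rng.uniform(size=need)
            frac = np.where(
                region == 0,
                u * half_end,
                np.where(region == 1, half_end + u * (1 - 2 * half_end),
                         1 - half_end + u * half_end),
            )
            cand = np.clip((frac * length).astype(np.int64), 1, int(length))
            pos = np.unique(np.concatenate([pos, cand]))
        if len(pos) > m:  # unique() can overshoot only via the top-up loop
            pos = rng.choice(pos, size=m, replace=False)
            pos.sort()
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))

    table = pd.concat(rows, ignore_index=True)
    cm = {c: config.cm_per_mb for c in chroms}
    return MarkerMap(table, dict(config.chrom_lengths), cm)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _gamete_phases(
    rng: np.random.Generator,
    gen_pos_cm: np.ndarray,
    map_length_cm: float,
    n_gametes: int,
) -> np.ndarray:
    """Founder-phase (0/1) per gamete at each genetic position.

    Crossover counts per gamete are Poisson with mean = map length in
    Morgans; crossover positions are uniform on the map (no interference),
    which realises the Haldane map function between any two positions.
    """
    starts = rng.integers(0, 2, size=n_gametes)
    counts = rng.poisson(map_length_cm / 100.0, size=n_gametes)
    xo = rng.uniform(0.0, map_length_cm, size=int(counts.sum()))
    gid = np.repeat(np.arange(n_gametes), counts)
    phases = np.empty((n_gametes, len(gen_pos_cm)), dtype=np.int8)
    for j, p in enumerate(gen_pos_cm):
        crossings = np.bincount(gid[xo < p], minlength=n_gametes)
        phases[:, j] = (starts + crossings) % 2
    return phases


def simulate_f2(
    marker_map: MarkerMap,
    loci: list[CausalLocus],
    config: PopulationConfig,
) -> GenotypeMatrix:
    """Simulate an F2 population on the marker map.

    Founders are fixed for alternate alleles at every marker, except a
    ``residual_founder_het`` fraction of markers at which the mutant-stock
    founder is heterozygous for a second minor allele (each F2 individual's
    F1 parent inherits one of the two stock alleles, so the population shows
    occasional tri-allelic sites).  Causal-locus genotypes are simulated on
    the same gametes (full linkage to neighbouring markers) and recorded
    undegraded in ``causal_genotypes``.
    """
    if len(marker_map) == 0:
        raise InvalidInputError("marker map is empty")
    for loc in loci:
        if loc.chromosome not in marker_map.chrom_lengths:
            raise InvalidInputError(f"causal locus {loc.name} on unknown chromosome")
        if not 1 <= loc.position <= marker_map.chrom_lengths[loc.chromosome]:
            raise InvalidInputError(f"causal locus {loc.name} outside its chromosome")

    rng = stage_rng(config.seed, "meiosis")
    n = config.n_individuals
    samples = [f"F2_{i + 1:04d}" for i in range(n)]

    # per-chromosome position lists: markers + causal loci
    chrom_tables: dict[int, pd.DataFrame] = {
        int(c): grp.reset_index() for c, grp in marker_map.table.groupby("chrom")
    }
    marker_dosage = np.zeros((len(marker_map), n), dtype=np.int8)
    causal_dosage = {loc.name: np.zeros(n, dtype=np.int8) for loc in loci}

    for chrom in sorted(marker_map.chrom_lengths):
        grp = chrom_tables.get(chrom)
        mpos = grp["pos"].to_numpy() if grp is not None else np.empty(0, dtype=int)
        midx = grp["index"].to_numpy() if grp is not None else np.empty(0, dtype=int)
        closs = [loc for loc in loci if loc.chromosome == chrom]
        all_bp = np.concatenate([mpos, [loc.position for loc in closs]])
        if all_bp.size == 0:
            continue
        gen_pos = marker_map.genetic_positions(chrom, all_bp)
        L = marker_map.genetic_length(chrom)
        phases = _gamete_phases(rng, gen_pos, L, 2 * n)
        dosage = phases[0::2] + phases[1::2]  # (n, n_pos) copies of founder-1 allele
        if len(mpos):
            marker_dosage[midx] = dosage[:, : len(mpos)].T
        for k, loc in enumerate(closs):
            causal_dosage[loc.name] = dosage[:, len(mpos) + k].astype(np.int8)

    # allele letters: founder 0 -> 'A'; founder 1 -> 'B', or 'C' at residual-het
    # markers depending on which stock allele the individual's F1 inherited
    het_sites = rng.uniform(size=len(marker_map)) < config.residual_founder_het
    stock_letter = np.full((len(marker_map), n), "B", dtype="U1")
    if het_sites.any():
        draws = rng.integers(0, 2, size=(int(het_sites.sum()), n))
        stock_letter[het_sites] = np.where(draws == 0, "B", "C")

    d = marker_dosage
    calls = np.empty(d.shape, dtype="U2")
    calls[d == 0] = "AA"
    het = d == 1
    calls[het] = np.char.add("A", stock_letter[het])
    hom = d == 2
    calls[hom] = np.char.add(stock_letter[hom], stock_letter[hom])

    causal = pd.DataFrame(
        {s: [int(causal_dosage[loc.name][i]) for loc in loci] for i, s in enumerate(samples)},
        index=[loc.name for loc in loci],
    )
    g = code_numeric(marker_map, samples, calls, causal_genotypes=causal)
    return g


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

def degrade_calls(g: GenotypeMatrix, config: PopulationConfig) -> GenotypeMatrix:
    """Mask calls as missing and miscall heterozygotes as random homozygotes.

    Entries become missing with probability ``missing_rate``; surviving
    heterozygote entries are flipped to a homozygote of one of their two
    alleles with probability ``het_miscall_rate``.  Codes and MAF are
    recomputed from the degraded calls; causal truth is never degraded.
    """
    rng = stage_rng(config.seed, "degrade")
    codes = g.codes.copy()
    shape = codes.shape

    if g.raw_calls is not None:
        raw = g.raw_calls.copy()
        a1, a2, _ = _raw_split(raw)
        het = (a1 != a2) & ~np.isnan(codes)
        flip = het & (rng.uniform(size=shape) < config.het_miscall_rate)
        pick_first = rng.integers(0, 2, size=shape).astype(bool)
        chosen = np.where(pick_first, a1, a2)
        raw[flip] = np.char.add(chosen[flip], chosen[flip])
        miss = rng.uniform(size=shape) < config.missing_rate
        raw[miss] = "NA"
        recoded = code_numeric(
            g.markers, g.samples, raw, causal_genotypes=g.causal_genotypes
        )
        # keep the original map even if a marker went all-missing
        if recoded.n_markers != g.n_markers:
            codes_full = np.full(shape, np.nan)
            maf_full = np.full(g.n_markers, np.nan)
            kept = g.markers.table.merge(
                recoded.markers.table.assign(_row=np.arange(recoded.n_markers)),
                on=["chrom", "pos"], how="left",
            )["_row"]
            for i, r in enumerate(kept):
                if not np.isnan(r):
                    codes_full[i] = recoded.codes[int(r)]
                    maf_full[i] = recoded.maf[int(r)]
            return dc_replace(
                g, codes=codes_full, raw_calls=raw, maf=maf_full
            )
        return dc_replace(
            g, codes=recoded.codes, raw_calls=raw, maf=recoded.maf
        )

    # codes-only path
    het = codes == 1.0
    flip = het & (rng.uniform(size=shape) < config.het_miscall_rate)
    codes[flip] = rng.choice([0.0, 2.0], size=int(flip.sum()))
    miss = rng.uniform(size=shape) < config.missing_rate
    codes[miss] = np.nan
    out = dc_replace(g, codes=codes)
    from .genotypes import recompute_maf

    return recompute_maf(out)


def _raw_split(raw: np.ndarray):
    from .genotypes import _split_alleles

    return _split_alleles(raw)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

#: Fixed within-class compound composition (weights sum to 1 in each group).
ACYL_WEIGHTS = {"C3MG": 0.55, "Pg3MG": 0.12, "ID6": 0.08, "Pn3MG_C3DMG": 0.18, "Pg3DMG": 0.07}
NONACYL_WEIGHTS = {"C3G": 0.62, "Pg3G": 0.18, "Pn3G": 0.20}


def simulate_phenotypes(
    g: GenotypeMatrix,
    loci: list[CausalLocus],
    config: PopulationConfig,
) -> PhenotypeTable:
    """Generate phenotypes from the recorded causal genotypes.

    AC is the baseline plus each locus's shift (applied where its mode
    condition holds), multiplied by unit-mean log-normal noise (right skew).
    Acylation percentage is drawn from the mutant-class normal when the
    reduced-acylation locus is homozygous recessive, else from the wild-type
    class.  Per-compound peak areas are decomposed from AC and acylation
    percentage so that trait derivation recovers both exactly; two replicate
    rows are produced with a common multiplicative factor per replicate whose
    spread is calibrated so the expected two-replicate CV equals
    ``replicate_cv_pct``.
    """
    if g.causal_genotypes is None:
        raise InvalidInputError("genotype matrix carries no causal truth")
    acyl_loci = [loc for loc in loci if loc.is_acylation_locus]
    if len(acyl_loci) != 1:
        raise InvalidConfigError("exactly one locus must be the reduced-acylation locus")
    for loc in loci:
        for trait in loc.effects:
            if trait != "AC":
                raise InvalidConfigError(f"unknown trait {trait!r} in effects of {loc.name}")

    rng = stage_rng(config.seed, "phenotypes")
    n = g.n_samples
    samples = g.samples

    rec_dosage = {}
    for loc in loci:
        d = g.causal_genotypes.loc[loc.name, samples].to_numpy(dtype=int)
        rec_dosage[loc.name] = d if loc.recessive_founder == 1 else 2 - d

    ac_true = np.full(n, config.ac_baseline)
    for loc in loci:
        shift = loc.effects.get("AC", 0.0)
        if shift:
            ac_true = ac_true + shift * loc.condition(rec_dosage[loc.name])
    ac_true = np.maximum(ac_true, 0.0)
    sigma = config.ac_noise_sigma
    if sigma > 0:
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
        ac = ac_true * noise
    else:
        ac = ac_true.copy()

    mut = acyl_loci[0].condition(rec_dosage[acyl_loci[0].name])
    means = np.where(mut, config.acylation_mut_mean, config.acylation_wt_mean)
    acyl_pct = means + (
        rng.normal(0.0, config.acylation_sd, size=n) if config.acylation_sd > 0 else 0.0
    )
    acyl_pct = np.clip(acyl_pct, 0.0, 100.0)

    # decompose into compound areas (total area proportional to AC)
    total_area = ac / config.standard_ac * config.standard_total_area
    acyl_area = total_area * acyl_pct / 100.0
    nonacyl_area = total_area - acyl_area
    areas = pd.DataFrame(index=samples, columns=list(COMPOUNDS), dtype=float)
    for c in ACYLATED:
        areas[c] = acyl_area * ACYL_WEIGHTS[c]
    for c in NON_ACYLATED:
        areas[c] = nonacyl_area * NONACYL_WEIGHTS[c]

    # replicates: one multiplicative factor per (sample, replicate); relative
    # sd s gives E[two-replicate CV] = s * sqrt(2/pi), so calibrate s up
    s_rel = (config.replicate_cv_pct / 100.0) * math.sqrt(math.pi / 2.0)
    factors = 1.0 + (rng.normal(0.0, s_rel, size=(n, 2)) if s_rel > 0 else np.zeros((n, 2)))
    factors = np.maximum(factors, 0.01)
    # centre the pair so the replicate mean reproduces the generated areas
    factors = factors / factors.mean(axis=1, keepdims=True)

    peak_rows = []
    for i, smpl in enumerate(samples):
        for r in (1, 2):
            row = {"sample": smpl, "replicate": r}
            for c in COMPOUNDS:
                row[c] = areas.at[smpl, c] * factors[i, r - 1]
            peak_rows.append(row)
    peaks = pd.DataFrame(peak_rows)

    # kernel-marker scores from causal truth: speckling segregates on ears of
    # plants heterozygous at the colored-aleurone locus
    r1_score = (
        (g.causal_genotypes.loc["r1", samples].to_numpy(dtype=int) == 1).astype(int)
        if "r1" in g.causal_genotypes.index
        else np.zeros(n, dtype=int)
    )
    table = pd.DataFrame(
        {
            "sample": samples,
            "ac_true": ac_true,
            "ac_mg_kg": ac,
            "acylation_pct": acyl_pct,
            "is_reduced_acylation": mut.astype(int),
            "r1_score": r1_score,
        }
    )
    for loc in loci:
        table[f"{loc.name}_recessive"] = (rec_dosage[loc.name] == 2).astype(int)
        table[f"{loc.name}_dosage"] = rec_dosage[loc.name]
    if "c1" in [loc.name for loc in loci]:
        table["c1_score"] = table["c1_recessive"]
    return PhenotypeTable(peaks=peaks, table=table)


def write_phenotype_tsv(ph: PhenotypeTable, path, header_comment: str | None = None) -> None:
    """One row per sample-replicate: peak areas plus per-sample truth columns."""
    merged = ph.peaks.merge(ph.table, on="sample", how="left")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        merged.to_csv(fh, sep="\t", index=False)


def read_phenotype_tsv(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    peak_cols = ["sample", "replicate"] + [c for c in COMPOUNDS if c in df.columns]
    peaks = df[peak_cols].copy()
    truth_cols = [c for c in df.columns if c not in peak_cols or c == "sample"]
    table = df.loc[df["replicate"] == 1, truth_cols].reset_index(drop=True)
    return PhenotypeTable(peaks=peaks, table=table)
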
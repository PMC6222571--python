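"""Numeric genotype coding, sample/site filters, and marker-spacing stats.

Raw genotype calls are unordered allele pairs ("AA", "AG", ...; "NA" for
missing).  They are converted to the GBS-style numeric coding used for the
scans: at each marker the most frequent allele in the population is the major
allele, the major homozygote is coded 2, any heterozygote 1, and every other
homozygote 0 -- third and fourth alleles at a site (residual founder
heterozygosity) are pooled with the minor class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InvalidInputError
from .genome import MarkerMap

log = logging.getLogger(__name__)

MISSING_CALL = "NA"


@dataclass
class GenotypeMatrix:
    """Markers x samples genotype data with raw-call and numeric layers.

    Attributes
    ----------
    markers : MarkerMap aligned row-for-row with the matrices.
    samples : ordered sample labels (columns).
    codes : float array (n_markers, n_samples); values in {0, 1, 2}, NaN for
        missing.
    raw_calls : optional array of unordered allele-pair strings ('<U2'),
        ``"NA"`` for missing.
    maf : per-marker minor-allele frequency in [0, 0.5] (major vs pooled-minor
        collapse), NaN where no calls.
    causal_genotypes : optional DataFrame (causal locus name x sample) holding
        the simulator's true mutant-allele dosage {0, 1, 2}; never degraded.
    """

    markers: MarkerMap
    samples: list[str]
    codes: np.ndarray
    raw_calls: np.ndarray | None = None
    maf: np.ndarray | None = None
    causal_genotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.markers), len(self.samples)):
            raise InvalidInputError("codes shape does not match markers x samples")
        ok = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not ok.all():
            raise InvalidInputError("codes must be 0, 1, 2 or NaN")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return np.isnan(self.codes).mean(axis=0)


def _split_alleles(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an '<U2' call array into first/second allele chars + missing mask."""
    arr = np.asarray(raw, dtype="U2")
    missing = (arr == MISSING_CALL) | (arr == "") | (arr == "N")
    as_bytes = np.ascontiguousarray(arr.astype("S2"))
    # 'S2' is exactly two bytes per element; reinterpret as allele pairs
    pairs = as_bytes.view("S1").reshape(*arr.shape, 2)
    a1 = pairs[..., 0].astype("U1")
    a2 = pairs[..., 1].astype("U1")
    a2 = np.where(a2 == "", a1, a2)  # single-letter call means homozygote
    return a1, a2, missing


def code_numeric(
    markers: MarkerMap,
    samples: list[str],
    raw_calls: np.ndarray,
    causal_genotypes: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Convert raw allele-pair calls to the numeric {0, 1, 2} coding.

    The major allele at a marker is the most frequent allele across the
    population (ties broken lexicographically).  Major homozygote -> 2,
    heterozygote -> 1, any other homozygote -> 0.  Markers where every call is
    missing are excluded with a logged warning.  MAF is the frequency of the
    pooled non-major class, folded to [0, 0.5].
    """
    raw = np.asarray(raw_calls, dtype="U2")
    if raw.shape != (len(markers), len(samples)):
        raise InvalidInputError("raw_calls shape does not match markers x samples")
    a1, a2, missing = _split_alleles(raw)

    n_markers = len(markers)
    codes = np.full(raw.shape, np.nan)
    maf = np.full(n_markers, np.nan)
    keep = np.ones(n_markers, dtype=bool)
    for i in range(n_markers):
        obs = ~missing[i]
        if not obs.any():
            keep[i] = False
            continue
        alleles = np.concatenate([a1[i, obs], a2[i, obs]])
        uniq, counts = np.unique(alleles, return_counts=True)
        # most frequent allele; ties broken lexicographically (np.unique sorts)
        major = uniq[np.argmax(counts)]
        p_major = counts.max() / counts.sum()
        maf[i] = min(p_major, 1.0 - p_major)
        hom_major = obs & (a1[i] == major) & (a2[i] == major)
        het = obs & (a1[i] != a2[i])
        codes[i, hom_major] = 2.0
        codes[i, het] = 1.0
        codes[i, obs & ~hom_major & ~het] = 0.0

    if not keep.all():
        log.warning("excluding %d marker(s) with all calls missing", (~keep).sum())
        markers = MarkerMap(
            markers.table.loc[keep].reset_index(drop=True),
            markers.chrom_lengths,
            markers.cm_per_mb,
        )
        raw, codes, maf = raw[keep], codes[keep], maf[keep]

    return GenotypeMatrix(
        markers=markers,
        samples=list(samples),
        codes=codes,
        raw_calls=raw,
        maf=maf,
        causal_genotypes=causal_genotypes,
    )


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Drop markers with MAF below ``threshold`` (boundary value kept)."""
    if not 0.0 <= threshold <= 0.5:
        raise InvalidInputError("MAF threshold must lie in [0, 0.5]")
    if g.maf is None:
        raise InvalidInputError("matrix has no MAF layer; run code_numeric first")
    keep = g.maf >= threshold
    markers = MarkerMap(
        g.markers.table.loc[keep].reset_index(drop=True),
        g.markers.chrom_lengths,
        g.markers.cm_per_mb,
    )
    return replace(
        g,
        markers=markers,
        codes=g.codes[keep],
        raw_calls=None if g.raw_calls is None else g.raw_calls[keep],
        maf=g.maf[keep],
    )


def filter_samples_by_missing(
    g: GenotypeMatrix, max_missing: float = 0.80
) -> GenotypeMatrix:
    """Drop samples whose missing fraction strictly exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise InvalidInputError("max_missing must lie in [0, 1]")
    frac = g.missing_fraction_per_sample()
    keep = frac <= max_missing
    if not keep.any():
        raise EmptyResultError("all samples exceed the missing-data threshold")
    dropped = int((~keep).sum())
    if dropped:
        log.info("excluding %d sample(s) over %.0f%% missing", dropped, 100 * max_missing)
    causal = g.causal_genotypes
    samples = [s for s, k in zip(g.samples, keep) if k]
    return replace(
        g,
        samples=samples,
        codes=g.codes[:, keep],
        raw_calls=None if g.raw_calls is None else g.raw_calls[:, keep],
        causal_genotypes=None if causal is None else causal.loc[:, samples],
    )


def recompute_maf(g: GenotypeMatrix) -> GenotypeMatrix:
    """Recompute MAF from the numeric codes (after sample filtering)."""
    n_obs = (~np.isnan(g.codes)).sum(axis=1)
    dosage = np.nansum(g.codes, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dosage / (2.0 * n_obs)
    maf = np.where(n_obs > 0, np.minimum(p, 1.0 - p), np.nan)
    return replace(g, maf=maf)


def spacing_stats(
    markers: MarkerMap, near_bp: int = 1_000_000, close_bp: int = 1_000
) -> dict[str, float]:
    """Adjacent-gap summary within chromosomes.

    Returns mean gap (bp), the fraction of gaps under ``near_bp`` (1 Mb
    default), and -- among those -- the fraction under ``close_bp`` (1 Kb
    default).  A map without within-chromosome pairs yields an empty summary
    (n_gaps = 0, NaN statistics).
    """
    gaps: list[np.ndarray] = []
    for _, grp in markers.table.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        if len(pos) >= 2:
            gaps.append(np.diff(pos))
    if not gaps:
        return {
            "n_gaps": 0,
            "mean_gap_bp": float("nan"),
            "frac_under_near": float("nan"),
            "frac_close_among_near": float("nan"),
        }
    all_gaps = np.concatenate(gaps)
    near = all_gaps < near_bp
    frac_close = float(np.mean(all_gaps[near] < close_bp)) if near.any() else float("nan")
    return {
        "n_gaps": int(all_gaps.size),
        "mean_gap_bp": float(all_gaps.mean()),
        "frac_under_near": float(near.mean()),
        "frac_close_among_near": frac_close,
    }


# ---------------------------------------------------------------------------
# TSV dialect: chrom, pos, then one column per sample with calls A/H/B/NA,
# where A = major homozygote (code 2), H = heterozygote, B = other homozygote.
# ---------------------------------------------------------------------------

_CODE_TO_CALL = {2.0: "A", 1.0: "H", 0.0: "B"}
_CALL_TO_CODE = {"A": 2.0, "H": 1.0, "B": 0.0, MISSING_CALL: np.nan}


def write_genotype_tsv(
    g: GenotypeMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    """Write the coded genotype matrix in the A/H/B/NA TSV dialect."""
    calls = np.full(g.codes.shape, MISSING_CALL, dtype="U2")
    for code, call in _CODE_TO_CALL.items():
        calls[g.codes == code] = call
    out = pd.concat(
        [
            g.markers.table[["chrom", "pos"]].reset_index(drop=True),
            pd.DataFrame(calls, columns=g.samples),
        ],
        axis=1,
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_genotype_tsv(
    path: str | Path,
    chrom_lengths: dict[int, int] | None = None,
) -> GenotypeMatrix:
    """Read a genotype TSV written by :func:`write_genotype_tsv`.

    Also accepts a simplified HapMap-like layout whose first columns are
    ``rs``, ``chrom``, ``pos`` -- the ``rs`` column is ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": int})
    if "rs" in df.columns:
        df = df.drop(columns=["rs"])
    if not {"chrom", "pos"}.issubset(df.columns):
        raise InvalidInputError("genotype TSV needs 'chrom' and 'pos' columns")
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    lengths = chrom_lengths
    if lengths is None:
        from .genome import B73V3_CHROM_LENGTHS

        lengths = {
            c: max(B73V3_CHROM_LENGTHS.get(c, 0), int(df.loc[df["chrom"] == c, "pos"].max()))
            for c in df["chrom"].unique()
        }
    markers = MarkerMap(df[["chrom", "pos"]].reset_index(drop=True), lengths)
    calls = df[sample_cols].to_numpy(dtype="U2")
    codes = np.full(calls.shape, np.nan)
    for call, code in _CALL_TO_CODE.items():
        codes[calls == call] = code
    g = GenotypeMatrix(markers=markers, samples=sample_cols, codes=codes)
    return recompute_maf(g)
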
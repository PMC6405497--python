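"""Marker variability and distance statistics on codominant genotype matrices.

Implements the summary statistics used to compare length-based against
sequence-based allele definitions: per-locus allele counts, observed and
expected heterozygosity, polymorphism information content (PIC), the
allele-sharing spectrum, pairwise allele-difference distances, principal
coordinates analysis, the Mantel test, and great-circle geographic
distances.

Formulas (p_i = allele frequencies among typed genotypes at a locus):

    He  = 1 - sum_i p_i^2                       (expected heterozygosity)
    Ho  = fraction heterozygous among typed     (observed heterozygosity)
    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

He uses the uncorrected form by default (the GenAlEx default); the unbiased
small-sample correction 2n/(2n-1) is available behind a flag.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio import DistanceMatrix as _SkbioDM

from .config_io import GenotypeMatrix, SampleEntry
from .errors import PipelineError

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Locus statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusStats:
    marker: str
    n_typed: int
    Na: int
    Ho: float
    He: float
    PIC: float
    missing_frac: float


def allele_frequencies(matrix: GenotypeMatrix, locus: str,
                       samples: Sequence[str] | None = None) -> dict[int, float]:
    counts: Counter = Counter()
    for s in samples if samples is not None else matrix.samples:
        call = matrix.get(s, locus)
        if call:
            counts.update(call)
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()} if total else {}


def _pic(freqs: Sequence[float]) -> float:
    p = np.asarray(freqs, dtype=float)
    sum_p2 = float(np.sum(p ** 2))
    sum_p4 = float(np.sum(p ** 4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - sum_p2 - (sum_p2 ** 2 - sum_p4)


def locus_stats(matrix: GenotypeMatrix,
                samples: Sequence[str] | None = None,
                unbiased: bool = False) -> list[LocusStats]:
    """Per-locus Na / Ho / He / PIC over typed genotypes.

    ``samples`` restricts the computation to a population subset. A
    monomorphic locus has Na=1, He=0, PIC=0.
    """
    samples = list(samples) if samples is not None else list(matrix.samples)
    out = []
    for locus in matrix.loci:
        calls = [matrix.get(s, locus) for s in samples]
        typed = [c for c in calls if c]
        n = len(typed)
        freqs = allele_frequencies(matrix, locus, samples)
        p = list(freqs.values())
        he = 1.0 - sum(x * x for x in p) if p else 0.0
        if unbiased and n > 0:
            he *= (2 * n) / (2 * n - 1)
        out.append(LocusStats(
            marker=locus,
            n_typed=n,
            Na=len(freqs),
            Ho=(sum(1 for c in typed if c[0] != c[1]) / n) if n else 0.0,
            He=he,
            PIC=_pic(p) if p else 0.0,
            missing_frac=1.0 - n / len(samples) if samples else 0.0,
        ))
    return out


def locus_stats_table(matrix: GenotypeMatrix, **kwargs) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in locus_stats(matrix, **kwargs)])


def filter_markers_by_missing(matrix: GenotypeMatrix,
                              max_missing: float = 0.50
                              ) -> tuple[GenotypeMatrix, list[str]]:
    """Drop markers unable to produce genotypes for most samples
    (missing fraction strictly above ``max_missing``)."""
    removed = [l for l in matrix.loci if matrix.missing_fraction(l) > max_missing]
    kept = [l for l in matrix.loci if l not in removed]
    if not kept:
        raise PipelineError("all markers removed by the missing-data filter")
    return matrix.subset_loci(kept), removed


def allele_sharing_spectrum(matrix: GenotypeMatrix) -> dict[int, int]:
    """Map (number of individuals carrying an allele) -> number of alleles.

    Each distinct (locus, allele) is counted once; an individual carries an
    allele if it occupies either chromosome slot. The spectrum's total equals
    the total number of distinct alleles.
    """
    carriers: dict[tuple[str, int], set[str]] = {}
    for (sample, locus), call in matrix.calls.items():
        for a in set(call):
            carriers.setdefault((locus, a), set()).add(sample)
    spectrum: Counter = Counter(len(v) for v in carriers.values())
    return dict(sorted(spectrum.items()))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with a metric label; NaN marks pairs with
    no co-typed loci."""

    ids: list[str]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise PipelineError("distance matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise PipelineError("distance matrix not symmetric")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _pair_distance(call_a, call_b) -> int:
    """2 minus the number of allele copies shared, counting multiplicity."""
    shared = sum((Counter(call_a) & Counter(call_b)).values())
    return 2 - shared


def pairwise_allele_distance(matrix: GenotypeMatrix
                             ) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Total and per-locus-mean allele-difference distances between samples.

    Per co-typed locus the contribution is 2 minus the number of shared
    allele copies (multiset intersection); pairs are compared over co-typed
    loci only (pairwise deletion). Returns ``(total, mean)``.
    """
    n = len(matrix.samples)
    total = np.zeros((n, n))
    mean = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            acc = 0
            shared_loci = 0
            for locus in matrix.loci:
                a = matrix.get(matrix.samples[i], locus)
                b = matrix.get(matrix.samples[j], locus)
                if a and b:
                    acc += _pair_distance(a, b)
                    shared_loci += 1
            total[i, j] = total[j, i] = acc if shared_loci else np.nan
            mean[i, j] = mean[j, i] = acc / shared_loci if shared_loci else np.nan
    return (DistanceMatrix(list(matrix.samples), total, "total differing alleles"),
            DistanceMatrix(list(matrix.samples), mean,
                           "mean differing alleles per locus"))


# ---------------------------------------------------------------------------
# Ordination and matrix correlation
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over retained (non-negative) axes


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis (Gower double-centering +
    eigendecomposition). Axes with negative eigenvalues are reported in
    ``eigenvalues`` but dropped from the coordinates."""
    if np.isnan(dm.values).any():
        raise PipelineError(
            "distance matrix has missing entries; filter markers or samples "
            "so every pair shares at least one typed locus before PCoA"
        )
    ord_res = _skbio_pcoa(_SkbioDM(dm.values, ids=dm.ids), method="eigh",
                          number_of_dimensions=len(dm.ids))
    eigvals = ord_res.eigvals.to_numpy()
    positive = eigvals > 1e-12 * max(1.0, abs(eigvals[0]))
    coords = ord_res.samples.to_numpy()[:, positive]
    prop = ord_res.proportion_explained.to_numpy()[positive]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = prop[:n_axes]
    columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=columns),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def mantel(genetic: DistanceMatrix, geographic: DistanceMatrix,
           permutations: int = 9999, seed: int | None = None
           ) -> tuple[float, float]:
    """One-tailed Mantel test of matrix correlation.

    r is the Pearson correlation over the upper-triangle entries; the
    p-value is the proportion of row/column permutations whose r reaches the
    observed one, with the identity permutation included in both numerator
    and denominator (so the smallest attainable p is 1/(permutations+1)).
    """
    if set(genetic.ids) != set(geographic.ids):
        raise PipelineError("Mantel test requires matching sample sets")
    geographic = geographic.subset(genetic.ids)
    x = genetic.condensed()
    y = geographic.condensed()
    if np.isnan(x).any() or np.isnan(y).any():
        raise PipelineError("Mantel test requires complete distance matrices")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PipelineError("Mantel r undefined for a constant distance matrix")

    def _pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    n = len(genetic.ids)
    iu = np.triu_indices(n, k=1)
    hits = 1  # identity permutation
    for _ in range(permutations - 1):
        perm = rng.permutation(n)
        y_perm = geographic.values[np.ix_(perm, perm)][iu]
        if _pearson(x, y_perm) >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / permutations


def geographic_distances(entries: Sequence[SampleEntry]
                         ) -> tuple[DistanceMatrix, list[str]]:
    """Great-circle (haversine) distances in km between sample coordinates.

    Samples without coordinates are excluded and returned in the second
    element.
    """
    with_coords = [e for e in entries if e.lon_lat is not None]
    excluded = [e.sample_id for e in entries if e.lon_lat is None]
    ids = [e.sample_id for e in with_coords]
    lon = np.radians([e.lon_lat[0] for e in with_coords])
    lat = np.radians([e.lon_lat[1] for e in with_coords])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, "geographic km"), excluded
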
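"""Contact-map derivation, subsampling, shuffling and genomic binning.

A contact map is the sparse, symmetric set of bead pairs found in spatial
proximity — either computed from a conformation with a contact radius, or
imported from single-cell Hi-C pairs records binned at a chosen genomic
resolution. Backbone-adjacent pairs (|i - j| = 1 within a chain) are always
excluded: they are in contact by construction and would duplicate backbone
bonds as restraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .conformations import Conformation

__all__ = [
    "ContactMap",
    "GenomicBinTable",
    "contacts_from_conformation",
    "contacts_per_bead",
    "sample_contacts",
    "sample_bulk_contacts",
    "shuffle_contact_map",
    "bin_pairs",
    "contacts_from_distance_map",
]

logger = logging.getLogger(__name__)


def _round_half_away(x: float) -> int:
    """Round half away from zero (so sample counts are reproducible)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ContactMap:
    """Unique unordered bead-index pairs over ``n_beads`` beads.

    ``pairs`` is an (M, 2) integer array with i < j, lexicographically
    sorted; ``multiplicity`` optionally counts repeated observations of a
    pair (bulk data), aligned with ``pairs``.
    """

    n_beads: int
    pairs: np.ndarray
    multiplicity: Optional[np.ndarray] = None

    def __post_init__(self):
        self.n_beads = int(self.n_beads)
        arr = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if arr.size:
            arr = np.sort(arr, axis=1)
            if (arr[:, 0] == arr[:, 1]).any():
                raise ValueError("self-pairs are not allowed")
            if arr.min() < 0 or arr.max() >= self.n_beads:
                raise ValueError("pair index out of range")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            arr = arr[order]
            if self.multiplicity is not None:
                self.multiplicity = np.asarray(self.multiplicity,
                                               dtype=np.int64)[order]
            dup = (np.diff(arr, axis=0) == 0).all(axis=1)
            if dup.any():
                raise ValueError("duplicate pairs")
        self.pairs = arr

    @property
    def n_contacts(self) -> int:
        return self.pairs.shape[0]

    def pair_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.pairs}

    def to_dense(self) -> np.ndarray:
        """Symmetric 0/1 matrix of the contacts."""
        m = np.zeros((self.n_beads, self.n_beads), dtype=np.uint8)
        if self.pairs.size:
            m[self.pairs[:, 0], self.pairs[:, 1]] = 1
            m[self.pairs[:, 1], self.pairs[:, 0]] = 1
        return m


def contacts_per_bead(cmap: ContactMap) -> float:
    """Unique contacts divided by the number of beads — the data-quality
    covariate the accuracy model is parameterized by."""
    if cmap.n_beads <= 0:
        raise ValueError("n_beads must be positive")
    return cmap.n_contacts / cmap.n_beads


def _adjacent_pairs(chains: Sequence[tuple[int, int]]) -> set[tuple[int, int]]:
    adj = set()
    for a, b in chains:
        for i in range(a, b - 1):
            adj.add((i, i + 1))
    return adj


def contacts_from_conformation(
    conf: Conformation, r_contact: float
) -> ContactMap:
    """All non-bonded bead pairs at Euclidean distance <= ``r_contact``.

    The comparison is inclusive; backbone-adjacent pairs are excluded.
    No periodic wrapping: conformations are compact real-space structures.
    """
    if r_contact <= 0:
        raise ValueError("r_contact must be positive")
    tree = cKDTree(conf.coords)
    pairs = tree.query_pairs(r_contact, output_type="ndarray")
    if pairs.size:
        adj = _adjacent_pairs(conf.chains)
        keep = np.array(
            [(int(i), int(j)) not in adj for i, j in np.sort(pairs, axis=1)],
            dtype=bool,
        )
        pairs = pairs[keep]
    return ContactMap(conf.n_beads, pairs)


def sample_contacts(cmap: ContactMap, fraction: float, seed: int = 0) -> ContactMap:
    """Uniform sample without replacement of a fraction of the contacts.

    Keeps ``round_half_away(fraction * n_contacts)`` pairs; models the
    random component of single-cell contact dropout.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    k = _round_half_away(fraction * cmap.n_contacts)
    rng = np.random.default_rng(seed)
    idx = rng.choice(cmap.n_contacts, size=k, replace=False) if k else []
    return ContactMap(cmap.n_beads, cmap.pairs[np.sort(np.asarray(idx, dtype=np.int64))])


def sample_bulk_contacts(
    cmap: ContactMap,
    fraction: float,
    max_per_bin: int = 2,
    seed: int = 0,
) -> ContactMap:
    """Weight-proportional sampling of bulk contacts with a per-bin cap.

    Pairs are drawn with probability proportional to their multiplicity;
    draws that would push either endpoint above ``max_per_bin`` accepted
    contacts are rejected. Sampling stops after
    ``round_half_away(fraction * total_multiplicity)`` accepted draws or
    when no admissible pair remains (short output is allowed and logged).
    Emulates converting a bulk (e.g. capture-C) profile into a plausible
    single-cell contact set.
    """
    if cmap.multiplicity is None:
        raise ValueError("sample_bulk_contacts requires multiplicities")
    if max_per_bin < 1:
        raise ValueError("max_per_bin must be >= 1")
    total = int(cmap.multiplicity.sum())
    target = _round_half_away(fraction * total)
    rng = np.random.default_rng(seed)
    weights = cmap.multiplicity.astype(float).copy()
    degree = np.zeros(cmap.n_beads, dtype=np.int64)
    chosen: list[int] = []
    while len(chosen) < target:
        wsum = weights.sum()
        if wsum <= 0:
            logger.info(
                "bulk sampling exhausted after %d of %d draws",
                len(chosen), target,
            )
            break
        p = weights / wsum
        k = int(rng.choice(len(weights), p=p))
        i, j = cmap.pairs[k]
        weights[k] = 0.0  # a pair enters the output at most once
        if degree[i] >= max_per_bin or degree[j] >= max_per_bin:
            continue
        degree[i] += 1
        degree[j] += 1
        chosen.append(k)
        # retire pairs whose endpoints are saturated
        if degree[i] >= max_per_bin:
            weights[(cmap.pairs[:, 0] == i) | (cmap.pairs[:, 1] == i)] = 0.0
        if degree[j] >= max_per_bin:
            weights[(cmap.pairs[:, 0] == j) | (cmap.pairs[:, 1] == j)] = 0.0
    chosen_idx = np.sort(np.array(chosen, dtype=np.int64))
    return ContactMap(cmap.n_beads, cmap.pairs[chosen_idx])


def shuffle_contact_map(cmap: ContactMap, seed: int = 0) -> ContactMap:
    """Diagonal-preserving shuffle: the randomized control map.

    For every separation s = j - i the output holds the same number of
    pairs at separation s as the input, re-placed uniformly at random among
    the valid (i, i + s) slots without duplication. Destroys the position
    of contacts while keeping the contact-frequency-vs-distance profile.
    """
    rng = np.random.default_rng(seed)
    n = cmap.n_beads
    out = []
    if cmap.pairs.size:
        seps = cmap.pairs[:, 1] - cmap.pairs[:, 0]
        for s in np.unique(seps):
            k = int((seps == s).sum())
            slots = n - int(s)
            assert k <= slots, "more pairs than slots at one separation"
            starts = rng.choice(slots, size=k, replace=False)
            for i in starts:
                out.append((int(i), int(i + s)))
    return ContactMap(n, np.array(out, dtype=np.int64).reshape(-1, 2))


@dataclass
class GenomicBinTable:
    """Tiling of chromosomes into fixed-size bins mapped onto bead indices.

    Bins tile each chromosome without overlap (last bin may be short);
    bead index <-> (chrom, bin) is a bijection, and each chromosome is one
    polymer chain.
    """

    chrom_sizes: dict[str, int]
    resolution: int
    bins: pd.DataFrame  # columns: chrom, start, end
    chains: list[tuple[int, int]]
    _offsets: dict[str, int]

    @classmethod
    def from_chrom_sizes(
        cls, chrom_sizes: dict[str, int], resolution: int
    ) -> "GenomicBinTable":
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        records = []
        chains = []
        offsets = {}
        pos = 0
        for chrom, size in chrom_sizes.items():
            n_bins = int(np.ceil(size / resolution))
            if n_bins == 0:
                raise ValueError(f"chromosome {chrom} shorter than one bin")
            offsets[chrom] = pos
            for b in range(n_bins):
                records.append(
                    (chrom, b * resolution, min((b + 1) * resolution, size))
                )
            chains.append((pos, pos + n_bins))
            pos += n_bins
        bins = pd.DataFrame(records, columns=["chrom", "start", "end"])
        return cls(dict(chrom_sizes), int(resolution), bins, chains, offsets)

    @property
    def n_beads(self) -> int:
        return len(self.bins)

    def bead_index(self, chrom: str, pos: int) -> int:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos <= self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + min(
            pos // self.resolution,
            int(np.ceil(self.chrom_sizes[chrom] / self.resolution)) - 1,
        )

    def bead_annotation(self) -> list[tuple[str, int, int]]:
        return list(self.bins.itertuples(index=False, name=None))


def bin_pairs(
    pairs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    resolution: int,
    trans: str = "keep",
) -> tuple[ContactMap, GenomicBinTable]:
    """Bin genomic contact records into a bead-level contact map.

    ``pairs`` needs columns chrom1, pos1, chrom2, pos2 (0-based). Each
    position maps to bin ``floor(pos / resolution)``; each chromosome is
    one chain. Intra-bin and bin-adjacent (same-chromosome) contacts are
    dropped, duplicates collapse to unique pairs with multiplicities.
    Records on unknown chromosomes or beyond the chromosome length are
    skipped and counted in the log. ``trans='drop'`` discards
    inter-chromosomal contacts.
    """
    if trans not in ("keep", "drop"):
        raise ValueError("trans must be 'keep' or 'drop'")
    table = GenomicBinTable.from_chrom_sizes(chrom_sizes, resolution)
    skipped = 0
    kept: list[tuple[int, int]] = []
    for chrom1, pos1, chrom2, pos2 in pairs[
        ["chrom1", "pos1", "chrom2", "pos2"]
    ].itertuples(index=False, name=None):
        if chrom1 not in chrom_sizes or chrom2 not in chrom_sizes:
            skipped += 1
            continue
        if not (0 <= pos1 <= chrom_sizes[chrom1]) or not (
            0 <= pos2 <= chrom_sizes[chrom2]
        ):
            skipped += 1
            continue
        if trans == "drop" and chrom1 != chrom2:
            continue
        i = table.bead_index(chrom1, int(pos1))
        j = table.bead_index(chrom2, int(pos2))
        if i == j:
            continue
        if chrom1 == chrom2 and abs(i - j) == 1:
            continue
        kept.append((min(i, j), max(i, j)))
    if skipped:
        logger.warning("bin_pairs: skipped %d out-of-range/unknown records",
                       skipped)
    if kept:
        arr = np.array(kept, dtype=np.int64)
        uniq, counts = np.unique(arr, axis=0, return_counts=True)
    else:
        uniq = np.empty((0, 2), dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    cmap = ContactMap(table.n_beads, uniq, multiplicity=counts)
    return cmap, table


def contacts_from_distance_map(
    dmap: np.ndarray, threshold: float
) -> tuple[ContactMap, np.ndarray]:
    """Threshold a (possibly incomplete) measured distance map into contacts.

    ``dmap`` is a symmetric matrix with NaN marking missing measurements
    (e.g. failed oligopaint probes). Returns the contact map (entries
    observed and <= threshold, backbone-adjacent excluded) and the boolean
    mask of missing entries, to be applied to the reconstructed map before
    comparison.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(dmap, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance map must be square")
    n = d.shape[0]
    mask = ~np.isfinite(d)
    mask |= mask.T  # symmetric missingness
    iu, ju = np.triu_indices(n, k=2)
    ok = (~mask[iu, ju]) & (d[iu, ju] <= threshold)
    pairs = np.column_stack([iu[ok], ju[ok]])
    return ContactMap(n, pairs), mask
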
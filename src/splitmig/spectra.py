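"""Joint allele-frequency spectra, folding, individual subsampling, and F_ST.

A joint SFS for two populations with ``n1`` and ``n2`` diploid individuals is
a ``(2*n1+1) x (2*n2+1)`` table whose cell ``(i, j)`` counts loci with ``i``
derived copies among the ``2*n1`` pop1 haplotypes and ``j`` among the ``2*n2``
pop2 haplotypes. The corner cells ``(0, 0)`` and ``(2n1, 2n2)`` carry no
polymorphism information and are always masked. Folding collapses each cell
onto its minor-allele image for use when the ancestral state is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import GenotypeDataset

__all__ = [
    "JointSFS",
    "FstResult",
    "build_joint_sfs",
    "fold",
    "subsample_individuals",
    "fst",
    "write_sfs",
    "read_sfs",
]


@dataclass
class JointSFS:
    """Two-population joint site-frequency spectrum.

    ``values`` holds counts (data) or expectations (model); ``mask`` is True
    for excluded cells. ``n1``/``n2`` are diploid sample sizes.
    """

    values: np.ndarray
    mask: np.ndarray
    folded: bool
    n1: int
    n2: int

    def __post_init__(self):
        expected = (2 * self.n1 + 1, 2 * self.n2 + 1)
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(f"spectrum shape must be {expected}")
        if np.any(self.values < 0):
            raise ValueError("spectrum entries must be non-negative")
        if not (self.mask[0, 0] and self.mask[-1, -1]):
            raise ValueError("corner cells (0,0) and (2n1,2n2) must be masked")

    @classmethod
    def from_values(cls, values, n1: int, n2: int, folded: bool = False) -> "JointSFS":
        values = np.asarray(values, dtype=float)
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 0] = True
        mask[-1, -1] = True
        if folded:
            h1, h2 = 2 * n1, 2 * n2
            i, j = np.indices(values.shape)
            mask |= (i + j) > (h1 + h2) / 2
        return cls(values=values, mask=mask, folded=folded, n1=n1, n2=n2)

    def total(self) -> float:
        """Sum of unmasked entries."""
        return float(self.values[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(
            values=self.values.copy(),
            mask=self.mask.copy(),
            folded=self.folded,
            n1=self.n1,
            n2=self.n2,
        )


@dataclass(frozen=True)
class FstResult:
    """Weir–Cockerham two-population F_ST as a ratio of summed components."""

    fst: float
    numerator: float  # sum over loci of the among-population component a
    denominator: float  # sum over loci of a + b


def build_joint_sfs(dataset: "GenotypeDataset", polarized: bool = False) -> JointSFS:
    """Count loci into the joint SFS; fold unless ``polarized``."""
    if dataset.n_loci == 0:
        raise ValueError("cannot build a spectrum from an empty dataset")
    h1 = 2 * dataset.n1
    counts1 = dataset.alleles[:, :h1].sum(axis=1)
    counts2 = dataset.alleles[:, h1:].sum(axis=1)
    values = np.zeros((h1 + 1, 2 * dataset.n2 + 1))
    np.add.at(values, (counts1, counts2), 1.0)
    sfs = JointSFS.from_values(values, n1=dataset.n1, n2=dataset.n2, folded=False)
    return sfs if polarized else fold(sfs)


def fold(sfs: JointSFS) -> JointSFS:
    """Fold onto minor-allele joint frequencies.

    Cell ``(i, j)`` with ``i + j`` below half the total haplotype count
    receives its own count plus that of the reflected cell
    ``(2n1 - i, 2n2 - j)``; cells exactly at half receive the average of the
    pair (so each diagonal cell keeps half of the combined mass and the total
    is conserved); cells beyond half are masked.
    """
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    h1, h2 = 2 * sfs.n1, 2 * sfs.n2
    half = (h1 + h2) / 2
    vals = np.zeros_like(sfs.values)
    reflected = sfs.values[::-1, ::-1]
    i, j = np.indices(sfs.values.shape)
    tot = i + j
    below = tot < half
    at = tot == half
    vals[below] = sfs.values[below] + reflected[below]
    vals[at] = (sfs.values[at] + reflected[at]) / 2.0
    mask = sfs.mask | sfs.mask[::-1, ::-1] | (tot > half)
    mask[0, 0] = True
    mask[-1, -1] = True
    return JointSFS(values=vals, mask=mask, folded=True, n1=sfs.n1, n2=sfs.n2)


def subsample_individuals(
    dataset: "GenotypeDataset", k: int, rng: np.random.Generator
) -> "GenotypeDataset":
    """Draw k diploid individuals per population, without replacement.

    Both haplotypes of each chosen individual are kept. Loci rendered
    monomorphic by the draw are removed (they could only fall in masked
    corner cells); the number removed is recorded in the provenance under
    ``dropped_monomorphic``.
    """
    from .simulate import GenotypeDataset

    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(dataset.n1, dataset.n2):
        raise ValueError(
            f"k={k} exceeds available individuals (n1={dataset.n1}, n2={dataset.n2})"
        )
    idx1 = np.sort(rng.choice(dataset.n1, size=k, replace=False))
    idx2 = np.sort(rng.choice(dataset.n2, size=k, replace=False)) + dataset.n1
    chosen = np.concatenate([idx1, idx2])
    hap_cols = np.concatenate([[2 * i, 2 * i + 1] for i in chosen])
    alleles = dataset.alleles[:, hap_cols]
    derived = alleles.sum(axis=1)
    keep = (derived >= 1) & (derived <= alleles.shape[1] - 1)
    provenance = dict(dataset.provenance)
    provenance["dropped_monomorphic"] = int((~keep).sum())
    provenance["subsampled_individuals"] = [dataset.sample_ids[i] for i in chosen]
    return GenotypeDataset(
        alleles=alleles[keep],
        sample_ids=[dataset.sample_ids[i] for i in chosen],
        sample_pops=[dataset.sample_pops[i] for i in chosen],
        locus_ids=[lid for lid, kp in zip(dataset.locus_ids, keep) if kp],
        provenance=provenance,
    )


def fst(dataset: "GenotypeDataset") -> FstResult:
    """Weir–Cockerham (1984) two-population F_ST, ratio of summed components.

    Haplotype-level variant: with phased biallelic haplotypes treated as
    independent allele draws, per locus the among-population component is

        a = (nbar/nc) * (s2 - (pbar*(1-pbar) - s2/2) / (nbar - 1))

    and the within-population component is

        b = (nbar/(nbar-1)) * (pbar*(1-pbar) - s2/2)

    where nbar is the mean haplotype sample size, nc the sample-size
    correction, pbar the weighted mean derived frequency and s2 the
    sample variance of frequencies across the two populations. F_ST is
    ``sum(a) / sum(a + b)`` over loci.
    """
    h1, h2 = 2 * dataset.n1, 2 * dataset.n2
    if h1 < 2 or h2 < 2:
        raise ValueError("need >= 2 haplotypes per population")
    d1 = dataset.alleles[:, :h1].sum(axis=1).astype(float)
    d2 = dataset.alleles[:, h1:].sum(axis=1).astype(float)
    p1, p2 = d1 / h1, d2 / h2
    r = 2
    nbar = (h1 + h2) / r
    nc = (h1 + h2 - (h1**2 + h2**2) / (h1 + h2)) / (r - 1)
    pbar = (h1 * p1 + h2 * p2) / (h1 + h2)
    s2 = (h1 * (p1 - pbar) ** 2 + h2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    a = (nbar / nc) * (s2 - b / nbar)
    num = float(a.sum())
    den = float((a + b).sum())
    if den == 0.0:
        raise ValueError("F_ST undefined: zero total variance (0/0)")
    return FstResult(fst=num / den, numerator=num, denominator=den)


def write_sfs(sfs: JointSFS, path) -> None:
    """Serialize a spectrum to plain text.

    Format: a comment header, then a line ``n1_hap n2_hap folded``, then the
    row-major value array, then the mask as 0/1 rows.
    """
    with open(path, "w") as fh:
        fh.write("# splitmig joint SFS: header is 'n1_hap n2_hap folded',"
                 " then values, then mask rows (1 = masked)\n")
        fh.write(f"{2 * sfs.n1} {2 * sfs.n2} {int(sfs.folded)}\n")
        for row in sfs.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        for row in sfs.mask:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    h1, h2, folded = (int(x) for x in lines[0].split())
    if h1 % 2 or h2 % 2:
        raise ValueError("haplotype counts must be even (diploid individuals)")
    nrow = h1 + 1
    values = np.array([[float(v) for v in ln.split()] for ln in lines[1 : 1 + nrow]])
    mask = np.array(
        [[bool(int(v)) for v in ln.split()] for ln in lines[1 + nrow : 1 + 2 * nrow]]
    )
    return JointSFS(values=values, mask=mask, folded=bool(folded), n1=h1 // 2, n2=h2 // 2)
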
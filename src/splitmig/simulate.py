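"""Synthetic two-population split-migration SNP datasets.

Generates genotype datasets with the structure the downstream analysis
assumes: unlinked biallelic loci, exactly one SNP per variable locus, phased
haplotypes, 100% call rate. This emulates one-SNP-per-locus marker panels
(e.g. SNPs thinned from ultraconserved-element loci) for two diverging
populations.

Conventions (inherited by the whole package): time is measured in units of
``2 N_ref`` generations backward from the present; deme sizes ``nu1``/``nu2``
are relative to the ancestral ``N_ref``; migration is symmetric with each
lineage switching demes at rate ``m/2`` per unit coalescent time; the
per-locus mutation parameter is ``theta_locus = 4 N_ref mu_locus`` and
mutations fall on a genealogy as a Poisson process of intensity
``theta_locus/2`` per unit branch length (infinite sites, no recombination
within a locus, loci independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SplitMigParams

__all__ = [
    "SimulationConfig",
    "Genealogy",
    "GenotypeDataset",
    "EmptyDatasetError",
    "simulate_genealogy",
    "simulate_dataset",
    "write_vcf",
    "read_vcf",
    "read_popmap",
    "write_popmap",
]


class EmptyDatasetError(RuntimeError):
    """Raised when no locus acquired a mutation (theta_locus too small)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for one synthetic dataset.

    ``L`` loci are attempted; only those with at least one mutation become
    variable loci in the output. ``theta_locus`` defaults to 0.08, the
    per-locus scale implied by aggregate theta estimates of roughly 120-260
    over ~2,000-2,700 variable UCE loci in the bird datasets this package
    emulates.
    """

    n1: int
    n2: int
    L: int
    params: SplitMigParams
    theta_locus: float = 0.08
    seed: int = 0
    keep_policy: str = "thin-random"  # one SNP chosen uniformly per variable locus

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("need at least one diploid individual per population")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (self.theta_locus > 0):
            raise ValueError("theta_locus must be > 0")
        if self.keep_policy != "thin-random":
            raise ValueError(f"unknown keep_policy {self.keep_policy!r}")


@dataclass
class Genealogy:
    """A realized structured-coalescent genealogy for one locus.

    ``branches`` holds one entry per non-root branch: a bitmask over sampled
    haplotypes (pop1 haplotypes first), the counts of subtended haplotypes in
    each population, and the branch length. Times are in units of ``2 N_ref``
    generations, increasing toward the root.
    """

    n1: int  # haplotypes sampled from pop1
    n2: int
    branches: list  # (leaf_mask:int, count1:int, count2:int, length:float)
    times: list  # coalescence event times, increasing
    total_length: float


def simulate_genealogy(
    n1: int, n2: int, params: SplitMigParams, rng: np.random.Generator
) -> Genealogy:
    """Simulate one structured-coalescent genealogy under split-migration.

    Backward in time there are two demes until the split time ``T`` (pairwise
    coalescence at rate ``1/nu_k`` within deme k, per-lineage migration at
    rate ``m/2``); at ``T`` all lineages merge into a single ancestral deme of
    relative size 1 with the standard coalescent thereafter.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one haplotype per population")
    for name in ("nu1", "nu2", "T", "m"):
        if not np.isfinite(getattr(params, name)):
            raise ValueError(f"non-finite parameter {name}")

    # live lineages: parallel lists of (mask, c1, c2, deme, birth_time)
    masks = [1 << i for i in range(n1 + n2)]
    c1 = [1] * n1 + [0] * n2
    c2 = [0] * n1 + [1] * n2
    deme = [0] * n1 + [1] * n2
    birth = [0.0] * (n1 + n2)
    branches: list = []
    times: list = []
    t = 0.0

    def coalesce(a: int, b: int, t: float):
        branches.append((masks[a], c1[a], c2[a], t - birth[a]))
        branches.append((masks[b], c1[b], c2[b], t - birth[b]))
        masks[a] |= masks[b]
        c1[a] += c1[b]
        c2[a] += c2[b]
        birth[a] = t
        for lst in (masks, c1, c2, deme, birth):
            lst[b] = lst[-1]
            lst.pop()
        times.append(t)

    while len(masks) > 1 and t < params.T:
        in0 = [i for i in range(len(masks)) if deme[i] == 0]
        in1 = [i for i in range(len(masks)) if deme[i] == 1]
        k0, k1 = len(in0), len(in1)
        rc0 = k0 * (k0 - 1) / 2.0 / params.nu1
        rc1 = k1 * (k1 - 1) / 2.0 / params.nu2
        rm = len(masks) * params.m / 2.0
        tot = rc0 + rc1 + rm
        if tot <= 0.0:
            break
        dt = rng.exponential(1.0 / tot)
        if t + dt >= params.T:
            break
        t += dt
        u = rng.random() * tot
        if u < rc0 + rc1:
            pool = in0 if u < rc0 else in1
            a, b = rng.choice(len(pool), size=2, replace=False)
            coalesce(pool[a], pool[b], t)
        else:
            j = rng.integers(len(masks))
            deme[j] = 1 - deme[j]
    t = max(t, params.T) if len(masks) > 1 else t
    while len(masks) > 1:
        k = len(masks)
        t += rng.exponential(2.0 / (k * (k - 1)))
        a, b = rng.choice(k, size=2, replace=False)
        coalesce(int(a), int(b), t)
    total = sum(br[3] for br in branches)
    return Genealogy(n1=n1, n2=n2, branches=branches, times=times, total_length=total)


@dataclass
class GenotypeDataset:
    """Phased biallelic genotypes for two labelled populations.

    ``alleles`` is loci x haplotypes over {0, 1} (ancestral = 0); haplotypes
    ``2i`` and ``2i+1`` belong to diploid individual ``i``; pop1 individuals
    come first. Every locus is variable and carries exactly one SNP.
    """

    alleles: np.ndarray
    sample_ids: list
    sample_pops: list  # per-individual population label, "pop1" or "pop2"
    locus_ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be loci x haplotypes")
        if self.alleles.shape[1] != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must be 2 x individuals")
        if len(self.sample_pops) != len(self.sample_ids):
            raise ValueError("sample_pops must match sample_ids")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1 with no missing calls")
        if self.alleles.shape[0]:
            derived = self.alleles.sum(axis=1)
            if derived.min() < 1 or derived.max() > self.alleles.shape[1] - 1:
                raise ValueError("every locus must be variable")

    @property
    def n1(self) -> int:
        return sum(1 for p in self.sample_pops if p == "pop1")

    @property
    def n2(self) -> int:
        return sum(1 for p in self.sample_pops if p == "pop2")

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[0]

    @property
    def haplotype_pops(self) -> list:
        return [p for p in self.sample_pops for _ in range(2)]


def simulate_dataset(config: SimulationConfig) -> GenotypeDataset:
    """Simulate a one-SNP-per-locus dataset of up to ``config.L`` loci.

    Each locus draws an independent genealogy; mutation count is Poisson with
    mean ``theta_locus/2 * total branch length``; loci with no mutation are
    dropped; one mutation, chosen uniformly among those present, defines the
    locus's SNP (random thinning). Per-locus RNG streams derive from the root
    seed so increasing ``L`` extends, rather than reshuffles, the loci.
    """
    h1, h2 = 2 * config.n1, 2 * config.n2
    children = np.random.SeedSequence(config.seed).spawn(config.L)
    rows = []
    locus_ids = []
    for locus, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        gen = simulate_genealogy(h1, h2, config.params, rng)
        n_mut = rng.poisson(config.theta_locus / 2.0 * gen.total_length)
        if n_mut == 0:
            continue
        lengths = np.array([br[3] for br in gen.branches])
        branch_idx = rng.choice(len(lengths), size=n_mut, p=lengths / lengths.sum())
        snp_branch = branch_idx[rng.integers(n_mut)]
        mask = gen.branches[snp_branch][0]
        row = np.fromiter(
            ((mask >> i) & 1 for i in range(h1 + h2)), dtype=np.int8, count=h1 + h2
        )
        rows.append(row)
        locus_ids.append(f"locus_{locus:06d}")
    if not rows:
        raise EmptyDatasetError(
            f"no variable loci among L={config.L} at theta_locus={config.theta_locus}"
        )
    sample_ids = [f"pop1_ind{i:02d}" for i in range(config.n1)] + [
        f"pop2_ind{i:02d}" for i in range(config.n2)
    ]
    provenance = {
        "seed": config.seed,
        "params": {
            "nu1": config.params.nu1,
            "nu2": config.params.nu2,
            "T": config.params.T,
            "m": config.params.m,
        },
        "theta_locus": config.theta_locus,
        "L_attempted": config.L,
        "L_variable": len(rows),
        "keep_policy": config.keep_policy,
    }
    return GenotypeDataset(
        alleles=np.array(rows, dtype=np.int8),
        sample_ids=sample_ids,
        sample_pops=["pop1"] * config.n1 + ["pop2"] * config.n2,
        locus_ids=locus_ids,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# VCF interchange (one record per locus, phased biallelic GT, no missing data)
# ---------------------------------------------------------------------------

def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write the dataset as an uncompressed VCF 4.2 with phased genotypes.

    One contig per locus (position 1), REF=A (ancestral), ALT=T (derived).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=splitmig\n")
        for lid in dataset.locus_ids:
            fh.write(f"##contig=<ID={lid},length=2>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        for row, lid in zip(dataset.alleles, dataset.locus_ids):
            gts = "\t".join(
                f"{row[2 * i]}|{row[2 * i + 1]}" for i in range(len(dataset.sample_ids))
            )
            fh.write(f"{lid}\t1\t{lid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_popmap(path) -> dict:
    """Read a two-column (sample_id, population) delimited text file."""
    popmap = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"malformed popmap line: {ln!r}")
            popmap[parts[0]] = parts[1]
    return popmap


def write_popmap(dataset: GenotypeDataset, path) -> None:
    with open(path, "w") as fh:
        for sid, pop in zip(dataset.sample_ids, dataset.sample_pops):
            fh.write(f"{sid}\t{pop}\n")


def read_vcf(path, pop_map: dict) -> GenotypeDataset:
    """Read phased biallelic SNPs from a VCF into a GenotypeDataset.

    ``pop_map`` maps sample id -> population label; exactly two labels must
    be present. Multiallelic records, missing genotypes and unphased
    genotypes are rejected (the datasets this pipeline models have none).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        missing = [s for s in samples if s not in pop_map]
        if missing:
            raise ValueError(f"samples absent from popmap: {missing}")
        pops = sorted(set(pop_map[s] for s in samples))
        if len(pops) != 2:
            raise ValueError(f"popmap must define exactly two populations, got {pops}")
        # pop1 individuals first, stable within-population order from the VCF
        order = [s for s in samples if pop_map[s] == pops[0]] + [
            s for s in samples if pop_map[s] == pops[1]
        ]
        rows, locus_ids, bad = [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                bad.append(f"{rec.chrom}:{rec.pos} not biallelic")
                continue
            row = np.empty(2 * len(order), dtype=np.int8)
            ok = True
            for i, s in enumerate(order):
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    bad.append(f"{rec.chrom}:{rec.pos} sample {s} missing GT")
                    ok = False
                    break
                if not call.phased:
                    bad.append(f"{rec.chrom}:{rec.pos} sample {s} unphased GT")
                    ok = False
                    break
                row[2 * i], row[2 * i + 1] = gt
            if ok:
                rows.append(row)
                locus_ids.append(rec.chrom)
    if bad:
        raise ValueError("invalid VCF records:\n" + "\n".join(bad))
    sample_pops = ["pop1" if pop_map[s] == pops[0] else "pop2" for s in order]
    return GenotypeDataset(
        alleles=np.array(rows, dtype=np.int8),
        sample_ids=order,
        sample_pops=sample_pops,
        locus_ids=locus_ids,
        provenance={"source": str(path), "pop_labels": {pops[0]: "pop1", pops[1]: "pop2"}},
    )
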
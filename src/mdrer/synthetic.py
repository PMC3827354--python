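"""Synthetic imbalanced case-control genotype data with planted epistasis.

Genotypes are drawn per SNP under Hardy-Weinberg equilibrium from its minor
allele frequency (code = number of minor alleles, 0/1/2). Disease status is
Bernoulli with probability given by a penetrance table over the causal loci's
genotype combination; individuals are drawn and kept until exactly the
requested numbers of cases and controls are collected (rejection sampling),
which leaves non-causal SNPs independent of status. The default profile
mirrors a chronic-dialysis mitochondrial D-loop study design: 77 SNPs,
193 cases, 704 controls (control:case ratio 3.65).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import GenotypeDataset

STUDY_N_SNPS = 77
STUDY_N_CASES = 193
STUDY_N_CONTROLS = 704


class SimulationError(RuntimeError):
    """Rejection sampling cannot reach the requested class quotas."""


@dataclass(frozen=True)
class PenetranceSpec:
    """Recipe for a case-control dataset with an embedded n-locus effect.

    ``penetrance`` maps every genotype tuple over ``causal_loci`` (each code
    in {0, 1, 2}) to a disease probability. ``mafs`` gives one minor allele
    frequency per SNP.
    """

    causal_loci: tuple[int, ...]
    penetrance: Mapping[tuple[int, ...], float]
    mafs: tuple[float, ...]
    n_cases: int
    n_controls: int
    seed: int = 0

    def __post_init__(self) -> None:
        loci = tuple(int(i) for i in self.causal_loci)
        mafs = tuple(float(m) for m in self.mafs)
        object.__setattr__(self, "causal_loci", loci)
        object.__setattr__(self, "mafs", mafs)
        if len(set(loci)) != len(loci):
            raise ValueError("causal loci must be distinct")
        if any(not 0 < m <= 0.5 for m in mafs):
            raise ValueError("minor allele frequencies must lie in (0, 0.5]")
        if any(i < 0 or i >= len(mafs) for i in loci):
            raise ValueError("causal locus index out of range of mafs")
        k = len(loci)
        missing = [
            g for g in itertools.product((0, 1, 2), repeat=k)
            if g not in self.penetrance
        ]
        if missing:
            raise ValueError(f"penetrance table missing genotype tuples: {missing[:5]}")
        if any(not 0 <= p <= 1 for p in self.penetrance.values()):
            raise ValueError("penetrance values must lie in [0, 1]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")

    @property
    def n_snps(self) -> int:
        return len(self.mafs)


def flat_penetrance(p: float, n_loci: int = 2) -> dict:
    """Null model: the same disease probability for every genotype."""
    return {g: p for g in itertools.product((0, 1, 2), repeat=n_loci)}


def carrier_penetrance(baseline: float, risk: float) -> dict:
    """Two-locus joint-carrier model: elevated risk iff both loci carry a
    minor allele (codes >= 1), baseline otherwise."""
    return {
        (g1, g2): risk if (g1 >= 1 and g2 >= 1) else baseline
        for g1, g2 in itertools.product((0, 1, 2), repeat=2)
    }


def xor_penetrance(baseline: float, risk: float) -> dict:
    """Two-locus XOR model: elevated risk iff exactly one locus carries a
    minor allele. Marginal single-SNP effects are weak by construction."""
    return {
        (g1, g2): risk if (g1 >= 1) != (g2 >= 1) else baseline
        for g1, g2 in itertools.product((0, 1, 2), repeat=2)
    }


def study_profile(
    seed: int = 0,
    penetrance: Mapping | None = None,
    causal_loci: tuple[int, ...] = (0, 1),
    n_snps: int = STUDY_N_SNPS,
    n_cases: int = STUDY_N_CASES,
    n_controls: int = STUDY_N_CONTROLS,
) -> PenetranceSpec:
    """Spec emulating the study's shape: 77 SNPs, 193 cases, 704 controls.

    MAFs are drawn once (seeded) from Uniform(0.05, 0.5); without an explicit
    penetrance table a null (flat 0.2) model is embedded, so the dataset has
    the study's imbalance but no planted effect.
    """
    rng = np.random.default_rng(seed)
    mafs = tuple(rng.uniform(0.05, 0.5, size=n_snps))
    if penetrance is None:
        penetrance = flat_penetrance(0.2, len(causal_loci))
    return PenetranceSpec(
        causal_loci=causal_loci,
        penetrance=penetrance,
        mafs=mafs,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


def generate(
    spec: PenetranceSpec,
    n_snps: int | None = None,
    *,
    max_draw_factor: int = 1000,
    snp_prefix: str = "SNP",
) -> GenotypeDataset:
    """Draw a dataset satisfying the spec's class quotas exactly.

    Causal genotypes are drawn first and disease status sampled from the
    penetrance table; individuals are kept in draw order until both quotas
    are met. Non-causal SNP columns are then filled independently of status.
    A spec whose penetrance makes a quota unreachable raises
    :class:`SimulationError` after ``max_draw_factor`` times the total sample
    size draws.
    """
    if n_snps is None:
        n_snps = spec.n_snps
    k = len(spec.causal_loci)
    if n_snps < k:
        raise ValueError(f"n_snps={n_snps} smaller than the {k} causal loci")
    if n_snps > spec.n_snps:
        raise ValueError(f"n_snps={n_snps} exceeds the {spec.n_snps} MAFs provided")

    rng = np.random.default_rng(spec.seed)
    pen = np.empty(3 ** k)
    for g, p in spec.penetrance.items():
        code = 0
        for gi in g:
            code = code * 3 + gi
        pen[code] = p
    causal_mafs = np.array([spec.mafs[i] for i in spec.causal_loci])

    total = spec.n_cases + spec.n_controls
    kept_geno: list[np.ndarray] = []
    kept_labels: list[np.ndarray] = []
    need_cases, need_controls = spec.n_cases, spec.n_controls
    drawn = 0
    while need_cases > 0 or need_controls > 0:
        if drawn > max_draw_factor * total:
            raise SimulationError(
                f"class quotas unreachable: after {drawn} draws still need "
                f"{need_cases} case(s) and {need_controls} control(s); "
                "check the penetrance table"
            )
        batch = max(4 * (need_cases + need_controls), 64)
        geno = rng.binomial(2, causal_mafs, size=(batch, k))
        code = np.zeros(batch, dtype=np.int64)
        for j in range(k):
            code = code * 3 + geno[:, j]
        status = (rng.random(batch) < pen[code]).astype(np.int64)
        drawn += batch
        # keep in draw order, stopping each class at its quota
        keep = np.zeros(batch, dtype=bool)
        case_pos = np.flatnonzero(status == 1)[:need_cases]
        control_pos = np.flatnonzero(status == 0)[:need_controls]
        keep[case_pos] = True
        keep[control_pos] = True
        kept_geno.append(geno[keep])
        kept_labels.append(status[keep])
        need_cases -= len(case_pos)
        need_controls -= len(control_pos)

    causal_geno = np.concatenate(kept_geno)
    labels = np.concatenate(kept_labels)

    genotypes = np.empty((total, n_snps), dtype=np.int64)
    causal_set = set(spec.causal_loci)
    for j, locus in enumerate(spec.causal_loci):
        genotypes[:, locus] = causal_geno[:, j]
    for j in range(n_snps):
        if j not in causal_set:
            genotypes[:, j] = rng.binomial(2, spec.mafs[j], size=total)
    names = tuple(f"{snp_prefix}{j + 1}" for j in range(n_snps))
    return GenotypeDataset(names, genotypes, labels)


def fixture_from_cells(
    cells: Mapping[tuple[int, ...], tuple[int, int]],
    n_pad_snps: int = 0,
    seed: int = 0,
    *,
    snp_names: Sequence[str] | None = None,
    snp_prefix: str = "SNP",
) -> GenotypeDataset:
    """Materialize a dataset whose designated-loci cell counts are ``cells``.

    The cell genotype tuples occupy the first ``len(tuple)`` SNP columns, so
    ``count_cells(dataset, range(k))`` reproduces ``cells`` exactly (empty
    cells excepted). ``n_pad_snps`` additional columns are filled with seeded
    random noise, independent of status.
    """
    items = sorted(cells.items())
    if not items:
        raise ValueError("need at least one cell")
    k = len(items[0][0])
    if any(len(g) != k for g, _ in items):
        raise ValueError("all cell genotype tuples must have the same length")
    if any(c < 0 or n < 0 for _, (c, n) in items):
        raise ValueError("cell counts must be non-negative")
    if all(c + n == 0 for _, (c, n) in items):
        raise ValueError("need at least one non-empty cell")

    rows, labels = [], []
    for g, (n_case, n_control) in items:
        rows.extend([g] * (n_case + n_control))
        labels.extend([1] * n_case + [0] * n_control)
    core = np.array(rows, dtype=np.int64).reshape(len(rows), k)
    rng = np.random.default_rng(seed)
    pad = rng.integers(0, 3, size=(len(rows), n_pad_snps))
    genotypes = np.hstack([core, pad])
    if snp_names is None:
        snp_names = tuple(f"{snp_prefix}{j + 1}" for j in range(k + n_pad_snps))
    return GenotypeDataset(tuple(snp_names), genotypes, np.array(labels))
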
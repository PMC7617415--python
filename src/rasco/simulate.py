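"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Three generators, all pure functions of (config, seed):

* ``generate_cohort`` — per-tumor driver genotypes and clinical covariates at
  the class frequencies, co-occurrence rates and covariate distributions of
  the combined published cohort (defaults mirror its summary table; see
  :class:`CohortConfig`).
* ``generate_read_counts`` — binomial sequencing read counts under the
  purity/copy-number/cell-fraction model, with the generating truth retained
  for recovery tests.
* ``generate_catalog`` — per-sample trinucleotide substitution catalogs drawn
  from 96-channel probability vectors, emitted on a random strand so that
  pyrimidine collapse is exercised.

Each generator derives an independent child stream from the root seed, so
adding one stage never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .braf_channels import CLASS1_CHANNELS, CLASS2_3_CHANNELS
from .clonality import expected_vaf
from .spectra import CHANNELS, CHANNEL_INDEX, _revcomp

__all__ = [
    "CohortConfig",
    "ReadSimConfig",
    "CatalogConfig",
    "generate_cohort",
    "generate_read_counts",
    "generate_catalog",
    "default_channel_vector",
]

# Observed protein changes per class, used as spelling pools when a tumor
# draws a mutation of that kind.
BRAF_CLASS1_VARIANTS = ("V600E",)
BRAF_CLASS2_VARIANTS = ("G469V", "G469A", "K601E", "G464V", "L597Q")
BRAF_CLASS3_VARIANTS = ("D594G", "G466V", "G596R", "N581S", "D594N")
KRAS_TYPICAL_VARIANTS = ("G12D", "G13D", "Q61H", "G12V")
KRAS_ATYPICAL_VARIANTS = ("L19F", "A146T", "V14I", "A146V", "A59T", "P34L", "G60D", "K117Q", "D33E")
NRAS_VARIANTS = ("G12D", "G12V", "Q61K")
NF1_TRUNCATING = ("R1362*", "Q1174*", "R440fs")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings; defaults mirror the combined-cohort summary.

    Frequencies are fractions of all profiled tumors; the remainder after the
    class and unclassified frequencies is BRAF wild-type.  Per-class maps are
    keyed "class1"/"class2"/"class3" (plus "wild_type" where relevant).
    """

    n_tumors: int = 6605
    class_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"class1": 0.107, "class2": 0.0047, "class3": 0.0122}
    )
    additional_ras_prob: Mapping[str, float] = field(
        default_factory=lambda: {"class1": 0.024, "class2": 0.29, "class3": 0.457}
    )
    atypical_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"class1": 0.82, "class2": 0.556, "class3": 0.78}
    )
    msi_prob: Mapping[str, float] = field(
        default_factory=lambda: {"class1": 0.524, "class2": 0.0, "class3": 0.0, "wild_type": 0.395}
    )
    distal_prob: Mapping[str, float] = field(
        default_factory=lambda: {"class1": 0.163, "class2": 0.625, "class3": 0.561, "wild_type": 0.657}
    )
    male_prob: Mapping[str, float] = field(
        default_factory=lambda: {"class1": 0.365, "class2": 0.63, "class3": 0.586, "wild_type": 0.581}
    )
    mean_age: Mapping[str, float] = field(
        default_factory=lambda: {"class1": 70.8, "class2": 67.3, "class3": 68.1, "wild_type": 66.2}
    )
    sd_age: float = 10.0
    stage_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "class1": (0.101, 0.389, 0.375, 0.136),
            "class2": (0.188, 0.375, 0.375, 0.062),
            "class3": (0.08, 0.18, 0.48, 0.26),
            "wild_type": (0.174, 0.306, 0.356, 0.164),
        }
    )
    # Ras drivers in BRAF wild-type tumors (so the cohort has a background).
    wt_ras_prob: float = 0.532
    wt_atypical_fraction: float = 0.192

    def validate(self) -> None:
        probs = [
            *self.class_frequencies.values(),
            *self.additional_ras_prob.values(),
            *self.atypical_fraction.values(),
            *self.msi_prob.values(),
            *self.distal_prob.values(),
            *self.male_prob.values(),
            self.wt_ras_prob,
            self.wt_atypical_fraction,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if sum(self.class_frequencies.values()) > 1:
            raise ValueError("class frequencies must sum to <= 1")
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")


def _norm(p: Sequence[float]) -> np.ndarray:
    # printed stage percentages can round to slightly off 1
    v = np.asarray(p, dtype=float)
    return v / v.sum()


def _child(seed: int, stream: str) -> np.random.Generator:
    # crc32, not hash(): the latter is salted per process and would break
    # the same-seed -> byte-identical-output contract.
    tag = zlib.crc32(stream.encode()) % (2**31)
    ss = np.random.SeedSequence([int(seed) % (2**31), tag])
    return np.random.default_rng(ss)


def generate_cohort(
    config: CohortConfig = CohortConfig(), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns (mutation table, clinical table)."""
    config.validate()
    rng = _child(seed, "cohort")
    classes = list(config.class_frequencies)
    freqs = np.array([config.class_frequencies[c] for c in classes])
    draw = rng.choice(
        len(classes) + 1,
        size=config.n_tumors,
        p=np.append(freqs, 1.0 - freqs.sum()),
    )
    mut_rows, clin_rows = [], []
    pools = {
        "class1": BRAF_CLASS1_VARIANTS,
        "class2": BRAF_CLASS2_VARIANTS,
        "class3": BRAF_CLASS3_VARIANTS,
    }
    for i, k in enumerate(draw):
        sid = f"T{i:05d}"
        group = classes[k] if k < len(classes) else "wild_type"
        if group != "wild_type":
            pc = str(rng.choice(pools[group]))
            mut_rows.append({"sample_id": sid, "gene": "BRAF", "protein_change": pc})
            p_add = config.additional_ras_prob[group]
            p_atyp = config.atypical_fraction[group]
        else:
            p_add = config.wt_ras_prob
            p_atyp = config.wt_atypical_fraction
        if rng.random() < p_add:
            if rng.random() < p_atyp:
                gene = str(rng.choice(["KRAS", "NRAS", "NF1"], p=[0.55, 0.3, 0.15]))
                pool = {
                    "KRAS": KRAS_ATYPICAL_VARIANTS,
                    "NRAS": NRAS_VARIANTS,
                    "NF1": NF1_TRUNCATING,
                }[gene]
            else:
                gene, pool = "KRAS", KRAS_TYPICAL_VARIANTS
            mut_rows.append(
                {"sample_id": sid, "gene": gene, "protein_change": str(rng.choice(pool))}
            )
        clin_rows.append(
            {
                "sample_id": sid,
                "msi_status": "MSI" if rng.random() < config.msi_prob.get(group, 0.0) else "MSS",
                "location": "distal" if rng.random() < config.distal_prob.get(group, 0.5) else "proximal",
                "age": round(float(rng.normal(config.mean_age.get(group, 68.0), config.sd_age)), 1),
                "sex": "male" if rng.random() < config.male_prob.get(group, 0.5) else "female",
                "stage": ["I", "II", "III", "IV"][
                    int(rng.choice(4, p=_norm(config.stage_probs.get(group))))
                ],
            }
        )
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "protein_change"])
    clinical = pd.DataFrame(clin_rows)
    return mutations, clinical


# Read-count simulation -----------------------------------------------------

_CN_STATES = ((1, 1), (2, 1), (2, 2), (3, 1))


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-count generator settings (one mutation per row of truth)."""

    n_mutations: int = 200
    purity_low: float = 0.3
    purity_high: float = 0.9
    depth_low: int = 200
    depth_high: int = 1000
    cn_states: Sequence[tuple[int, int]] = _CN_STATES
    cell_fraction: float = 1.0   # cancer-cell fraction of each mutation

    def validate(self) -> None:
        if self.depth_low < 1 or self.depth_high < self.depth_low:
            raise ValueError("depths must satisfy 1 <= low <= high")
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell fraction must be in (0, 1]")
        if not 0 < self.purity_low <= self.purity_high <= 1:
            raise ValueError("purities must satisfy 0 < low <= high <= 1")


def generate_read_counts(
    config: ReadSimConfig = ReadSimConfig(), seed: int = 0
) -> pd.DataFrame:
    """Simulate binomial read counts under the purity/CN/cell-fraction model.

    Returns one table holding both the observable columns (mutant_reads,
    total_reads, purity, major_cn, minor_cn) and the generating truth
    (n_mut, n_wt, cell_fraction, expected_vaf).
    """
    config.validate()
    rng = _child(seed, "reads")
    rows = []
    for i in range(config.n_mutations):
        purity = float(rng.uniform(config.purity_low, config.purity_high))
        depth = int(rng.integers(config.depth_low, config.depth_high + 1))
        major, minor = config.cn_states[int(rng.integers(len(config.cn_states)))]
        # mutation lands on the major or minor allele at random (mutant copies >= 1)
        n_mut = int(rng.choice([major, minor])) if minor >= 1 else major
        n_wt = major + minor - n_mut
        vaf_clonal = expected_vaf(purity, n_mut, n_wt)
        vaf = config.cell_fraction * vaf_clonal
        mutant = int(rng.binomial(depth, vaf)) if vaf > 0 else 0
        rows.append(
            {
                "mutation_id": f"M{i:05d}",
                "purity": purity,
                "major_cn": major,
                "minor_cn": minor,
                "n_mut": n_mut,
                "n_wt": n_wt,
                "cell_fraction": config.cell_fraction,
                "expected_vaf": vaf,
                "total_reads": depth,
                "mutant_reads": mutant,
            }
        )
    return pd.DataFrame(rows)


# Catalog simulation --------------------------------------------------------

def default_channel_vector(
    class1_mass: float = 0.0069, class2_3_mass: float = 0.129
) -> np.ndarray:
    """A 96-channel probability vector with configurable causal-channel mass.

    Default masses place 0.69% on the class 1 channel and 12.9% summed over
    the 16 class 2/3 channels (the whole-genome cohort means used to
    calibrate the generator), with the remainder flat over the other
    channels.
    """
    vec = np.zeros(96)
    i1 = [CHANNEL_INDEX[c.label] for c in CLASS1_CHANNELS.channels]
    i23 = [CHANNEL_INDEX[c.label] for c in CLASS2_3_CHANNELS.channels]
    vec[i1] = class1_mass / len(i1)
    vec[i23] += class2_3_mass / len(i23)
    rest = [i for i in range(96) if i not in set(i1) | set(i23)]
    vec[rest] = (1.0 - class1_mass - class2_3_mass) / len(rest)
    return vec


@dataclass(frozen=True)
class CatalogConfig:
    """Catalog generator settings."""

    n_samples: int = 10
    mutations_per_sample: int = 5000   # Poisson mean
    channel_probs: np.ndarray | None = None   # length 96; default vector if None

    def vector(self) -> np.ndarray:
        v = self.channel_probs if self.channel_probs is not None else default_channel_vector()
        v = np.asarray(v, dtype=float)
        if v.shape != (96,) or (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("channel_probs must be a 96-vector summing to 1")
        return v


def generate_catalog(config: CatalogConfig = CatalogConfig(), seed: int = 0) -> pd.DataFrame:
    """Draw per-sample substitution catalogs over the 96 channels.

    Each drawn channel is emitted either as its pyrimidine-strand context or
    as the reverse complement (random strand), so downstream collapse is
    exercised; fixed mutation counts (``mutations_per_sample``) are drawn
    per sample from a Poisson law.
    """
    vec = config.vector()
    rng = _child(seed, "catalog")
    rows = []
    for s in range(config.n_samples):
        n = int(rng.poisson(config.mutations_per_sample))
        idx = rng.choice(96, size=n, p=vec)
        flip = rng.random(n) < 0.5
        for j, ch_i in enumerate(idx):
            ch = CHANNELS[ch_i]
            context = ch.left + ch.ref + ch.right
            ref, alt = ch.ref, ch.alt
            if flip[j]:
                context = _revcomp(context)
                ref = {"A": "T", "C": "G", "G": "C", "T": "A"}[ref]
                alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[alt]
            rows.append(
                {"sample_id": f"S{s:03d}", "context": context, "ref": ref, "alt": alt}
            )
    return pd.DataFrame(rows, columns=["sample_id", "context", "ref", "alt"])
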
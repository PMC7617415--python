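"""96-channel trinucleotide mutation spectra and channel-activity statistics.

Single-base substitutions are binned by substitution type and flanking bases
into the conventional 96 channels, reported from the pyrimidine strand: a
substitution whose reference base is a purine is reverse-complemented before
labelling, so the channel of a mutation equals the channel of its
reverse-complement.  Channel labels follow the ``L[R>A]R`` convention and the
standard lexicographic ordering (C>A, C>G, C>T, T>A, T>C, T>G; flanks
A/C/G/T).

Per-sample raw channel counts are normalised to proportions summing to one,
so samples of different mutation burden are comparable.  The activity a
sample's mutational processes give to the channel(s) capable of generating a
particular driver substitution ("causal channels") is the sum of the
sample's weights over that channel set; a logistic regression of driver
presence on this proportion (with location, MSI status, age and sex as
covariates) asks whether tumors whose mutational processes favour the causal
context are more likely to carry the driver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MutationChannel",
    "SpectrumProfile",
    "CausalChannelSet",
    "CHANNELS",
    "CHANNEL_INDEX",
    "collapse_to_pyrimidine",
    "build_spectrum",
    "causal_channel_proportion",
    "fit_presence_logistic",
    "SeparationError",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_DNA = set("ACGT")
_PYRIMIDINES = ("C", "T")
_SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
_BASES = ("A", "C", "G", "T")


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MutationChannel:
    """One of the 96 pyrimidine-strand trinucleotide substitution channels."""

    ref: str          # pyrimidine: C or T
    alt: str
    left: str
    right: str

    def __post_init__(self):
        if self.ref not in _PYRIMIDINES:
            raise ValueError(f"channel reference must be a pyrimidine, got {self.ref}")
        if self.alt not in _DNA or self.alt == self.ref:
            raise ValueError(f"bad alternate base {self.alt}")
        if self.left not in _DNA or self.right not in _DNA:
            raise ValueError("flanks must be DNA bases")

    @property
    def label(self) -> str:
        return f"{self.left}[{self.ref}>{self.alt}]{self.right}"

    @classmethod
    def from_label(cls, label: str) -> "MutationChannel":
        # L[R>A]R
        if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
            raise ValueError(f"bad channel label {label!r}")
        return cls(ref=label[2], alt=label[4], left=label[0], right=label[6])


# Conventional ordering: substitution-major, then left flank, then right.
CHANNELS: tuple[MutationChannel, ...] = tuple(
    MutationChannel(ref=r, alt=a, left=l, right=rt)
    for (r, a) in _SUBSTITUTIONS
    for l in _BASES
    for rt in _BASES
)
CHANNEL_INDEX: dict[str, int] = {ch.label: i for i, ch in enumerate(CHANNELS)}
assert len(CHANNELS) == 96


def collapse_to_pyrimidine(context: str, ref: str, alt: str) -> MutationChannel:
    """Map a reference-strand substitution to its pyrimidine-strand channel."""
    if len(context) != 3 or set(context) - _DNA:
        raise ValueError(f"context must be a 3-mer over ACGT, got {context!r}")
    if ref not in _DNA or alt not in _DNA or ref == alt:
        raise ValueError(f"bad substitution {ref}>{alt}")
    if context[1] != ref:
        raise ValueError(f"context centre {context[1]!r} does not match ref {ref!r}")
    if ref in _PYRIMIDINES:
        return MutationChannel(ref=ref, alt=alt, left=context[0], right=context[2])
    rc = _revcomp(context)
    return MutationChannel(
        ref=_COMPLEMENT[ref], alt=_COMPLEMENT[alt], left=rc[0], right=rc[2]
    )


@dataclass(frozen=True)
class SpectrumProfile:
    """Normalised 96-channel spectrum for one sample."""

    sample_id: str
    raw_counts: np.ndarray       # int, length 96
    channel_weights: np.ndarray  # float, length 96, sums to 1 (or all-zero flag)
    empty: bool = False

    def weight(self, label: str) -> float:
        return float(self.channel_weights[CHANNEL_INDEX[label]])


def build_spectrum(
    catalog: Iterable[tuple[str, str, str]], sample_id: str = ""
) -> SpectrumProfile:
    """Bin a catalog of (context, ref, alt) substitutions into a spectrum."""
    counts = np.zeros(96, dtype=np.int64)
    for context, ref, alt in catalog:
        ch = collapse_to_pyrimidine(context, ref, alt)
        counts[CHANNEL_INDEX[ch.label]] += 1
    total = counts.sum()
    if total == 0:
        return SpectrumProfile(sample_id, counts, np.zeros(96), empty=True)
    return SpectrumProfile(sample_id, counts, counts / total)


def spectra_from_catalog(catalog: pd.DataFrame) -> list[SpectrumProfile]:
    """One spectrum per sample from a (sample_id, context, ref, alt) table."""
    out = []
    for sid, grp in catalog.groupby("sample_id", sort=True):
        out.append(
            build_spectrum(
                zip(grp["context"], grp["ref"], grp["alt"]), sample_id=str(sid)
            )
        )
    return out


def spectra_to_frame(spectra: Sequence[SpectrumProfile]) -> pd.DataFrame:
    df = pd.DataFrame(
        [s.channel_weights for s in spectra],
        columns=[ch.label for ch in CHANNELS],
    )
    df.insert(0, "sample_id", [s.sample_id for s in spectra])
    return df


@dataclass(frozen=True)
class CausalChannelSet:
    """The channel(s) whose mutations can generate a given driver class."""

    label: str
    channels: frozenset[MutationChannel]

    @classmethod
    def from_labels(cls, label: str, labels: Iterable[str]) -> "CausalChannelSet":
        return cls(label, frozenset(MutationChannel.from_label(s) for s in labels))


def causal_channel_proportion(
    spectrum: SpectrumProfile, channels: CausalChannelSet
) -> float:
    """Summed spectrum weight over a causal channel set (in [0, 1])."""
    idx = [CHANNEL_INDEX[ch.label] for ch in channels.channels]
    return float(spectrum.channel_weights[idx].sum())


class SeparationError(RuntimeError):
    """Logistic fit impossible or degenerate (e.g. single-class outcome)."""


def fit_presence_logistic(
    cohort: pd.DataFrame,
    outcome: str = "presence",
    exposure: str = "channel_proportion",
    covariates: Sequence[str] = ("location_distal", "mss", "age", "male"),
    penalized_fallback: bool = False,
) -> pd.DataFrame:
    """Logistic regression of driver presence on causal-channel activity.

    Covariate coding convention: location distal = 1, MSS = 1, male = 1.
    Returns a coefficient table (estimate, standard error, z, Wald p).
    Raises :class:`SeparationError` on a single-class outcome or detected
    complete separation (unless ``penalized_fallback``, which then refits
    with an L2 ridge penalty and marks the output).
    """
    y = cohort[outcome].astype(float).to_numpy()
    if y.min() == y.max():
        raise SeparationError("outcome has a single class; logistic fit impossible")
    cols = [exposure, *[c for c in covariates if c in cohort.columns]]
    X = sm.add_constant(cohort[cols].astype(float), has_constant="add")
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=0, maxiter=200)
        separated = (
            not np.isfinite(fit.bse).all()
            or np.abs(fit.params).max() > 50
            or not fit.mle_retvals.get("converged", True)
        )
    except Exception:
        separated = True
        fit = None
    if separated:
        if not penalized_fallback:
            raise SeparationError("complete or quasi-complete separation detected")
        fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        return pd.DataFrame(
            {"term": X.columns, "estimate": np.asarray(fit.params), "penalized": True}
        )
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "std_error": fit.bse.to_numpy(),
            "z": fit.tvalues.to_numpy(),
            "p_wald": fit.pvalues.to_numpy(),
        }
    )
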
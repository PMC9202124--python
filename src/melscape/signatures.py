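"""Trinucleotide-context mutation catalogs and signature refitting.

Single-base substitutions are tabulated over 96 classes: the six pyrimidine
substitutions (C>A, C>G, C>T, T>A, T>C, T>G) by the 16 combinations of 5'
and 3' flanking bases. Substitutions reported on the purine strand are
folded to the reverse complement. Refitting decomposes a sample catalog
into nonnegative exposures to a fixed, column-normalized reference
signature matrix by nonnegative least squares; no de novo extraction is
performed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: canonical 96-class ordering: substitution-major, then 5' base, then 3' base
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_LABEL_INDEX = {lbl: i for i, lbl in enumerate(CONTEXT_LABELS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substitution_label(ref: str, alt: str, context: str) -> str:
    """96-class label of one SNV, folding purine references to pyrimidine."""
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} inconsistent with ref {ref!r}")
    if ref in {"A", "G"}:
        context = revcomp(context)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationCatalog96:
    """96-class substitution counts for one sample."""

    counts: np.ndarray
    sample_id: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have exactly 96 entries")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS), name=self.sample_id)


@dataclass
class ExposureVector:
    """Nonnegative signature exposures and their fractions for one sample."""

    exposures: np.ndarray
    signature_names: tuple[str, ...]
    residual: float = 0.0

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    @property
    def fractions(self) -> Optional[np.ndarray]:
        """Exposure fractions, or None when the total exposure is zero."""
        t = self.total
        if t <= 0:
            return None
        return self.exposures / t

    def fraction_of(self, name: str) -> float:
        f = self.fractions
        if f is None:
            raise ValueError("zero total exposure: fractions undefined")
        return float(f[self.signature_names.index(name)])


def build_96_catalog(snvs: Iterable, sample_id: str = "") -> MutationCatalog96:
    """Tabulate SNVs (records with ref/alt/trinucleotide_context) into 96 bins.

    Records whose context is missing or inconsistent with the reference base
    are skipped and counted in ``n_skipped`` with a warning.
    """
    counts = np.zeros(96)
    skipped = 0
    for rec in snvs:
        ctx = getattr(rec, "trinucleotide_context", None)
        try:
            lbl = substitution_label(rec.ref, rec.alt, ctx or "")
        except (ValueError, KeyError):
            skipped += 1
            continue
        counts[_LABEL_INDEX[lbl]] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} SNVs with invalid context", stacklevel=2)
    return MutationCatalog96(counts, sample_id=sample_id, n_skipped=skipped)


def validate_signature_matrix(signatures: pd.DataFrame) -> pd.DataFrame:
    """Check a 96 x k reference matrix: row labels, nonnegativity, column sums."""
    if list(signatures.index) != list(CONTEXT_LABELS):
        signatures = signatures.reindex(list(CONTEXT_LABELS))
        if signatures.isna().any().any():
            raise ValueError("signature matrix rows do not cover the 96 classes")
    vals = signatures.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative signature entries")
    sums = vals.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must sum to 1")
    return signatures


def refit_signatures(
    catalog: MutationCatalog96, signatures: pd.DataFrame
) -> ExposureVector:
    """Nonnegative least-squares refit of a catalog onto fixed signatures.

    Minimizes ||catalog - S e||_2 subject to e >= 0. An all-zero catalog
    yields zero exposures (fractions undefined).
    """
    signatures = validate_signature_matrix(signatures)
    names = tuple(signatures.columns)
    if catalog.total == 0:
        return ExposureVector(np.zeros(len(names)), names, residual=0.0)
    S = signatures.to_numpy(dtype=float)
    e, resid = nnls(S, catalog.counts)
    return ExposureVector(e, names, residual=float(resid))


def synthetic_reference_signatures(
    n_flat: int = 4, seed: int = 0, concentration: float = 0.5
) -> pd.DataFrame:
    """Synthetic stand-in for a COSMIC-style SBS reference matrix.

    One UV-like column ("SBS7"), with its mass concentrated on C>T changes
    at dipyrimidine contexts (5' C or T), plus ``n_flat`` Dirichlet-drawn
    background columns ("SBSa", "SBSb", ...). Columns are normalized to sum
    to 1. Deterministic for a given seed. These are synthetic signatures for
    simulation and testing, not curated mutational processes.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    uv = np.zeros(96)
    for i, lbl in enumerate(CONTEXT_LABELS):
        if "[C>T]" in lbl:
            uv[i] = 8.0 if lbl[0] in "CT" else 0.4
        else:
            uv[i] = 0.05
    cols["SBS7"] = uv / uv.sum()
    for j in range(n_flat):
        w = rng.dirichlet(np.full(96, concentration))
        cols[f"SBS{chr(ord('a') + j)}"] = w
    return pd.DataFrame(cols, index=list(CONTEXT_LABELS))
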
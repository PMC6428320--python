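"""Pairwise genetic distances for aligned nucleotide sequences.

Implements the Kimura two-parameter (K80) distance and the uncorrected
p-distance with an explicit contract for gaps and ambiguity codes:
columns where either sequence carries a gap or any non-ACGT symbol are
excluded from the comparison (pairwise deletion, no fractional matching
of IUPAC ambiguities).

Pairs compared over fewer than ``min_sites`` columns, and pairs whose
transition/transversion proportions fall outside the K80 domain
(saturation), are *masked* rather than raised: the matrix keeps ``NaN``
at those cells and records the reason in a boolean mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteCounts",
    "DistanceMatrix",
    "site_counts",
    "kimura_k80",
    "p_distance",
    "distance_matrix",
    "write_long_tsv",
    "write_phylip",
]

# Encoding: A=0, C=1, G=2, T=3; anything else (gaps, N, IUPAC codes) = 255.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("U")] = 3
_ENCODE[ord("u")] = 3

# Purine flag for transition/transversion classification (A, G are purines).
_IS_PURINE = np.array([True, False, True, False], dtype=bool)

DEFAULT_MIN_SITES = 100


@dataclass(frozen=True)
class SiteCounts:
    """Transition/transversion proportions over the compared sites.

    P and Q are proportions of transitions and transversions among the L
    columns where both sequences carry an unambiguous base. They are
    undefined (NaN) when L = 0.
    """

    P: float
    Q: float
    L: int

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("L must be >= 0")
        if self.L > 0 and not (
            self.P >= 0 and self.Q >= 0 and self.P + self.Q <= 1 + 1e-12
        ):
            raise ValueError(f"invalid site proportions P={self.P} Q={self.Q}")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as uint8 codes (255 = excluded symbol)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def site_counts(a: str | np.ndarray, b: str | np.ndarray) -> SiteCounts:
    """Count transition/transversion proportions under pairwise deletion.

    Parameters
    ----------
    a, b:
        Aligned sequences of equal length (strings or pre-encoded arrays).

    Raises
    ------
    ValueError
        If the sequences differ in length.
    """
    xa = encode(a) if isinstance(a, str) else a
    xb = encode(b) if isinstance(b, str) else b
    if xa.shape != xb.shape:
        raise ValueError(f"unequal aligned lengths: {xa.size} != {xb.size}")
    ok = (xa != 255) & (xb != 255)
    L = int(ok.sum())
    if L == 0:
        return SiteCounts(float("nan"), float("nan"), 0)
    da, db = xa[ok], xb[ok]
    diff = da != db
    ts = diff & (_IS_PURINE[da] == _IS_PURINE[db])
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return SiteCounts(n_ts / L, n_tv / L, L)


def p_distance(c: SiteCounts) -> float:
    """Uncorrected proportion of differing sites (NaN when L = 0)."""
    if c.L == 0:
        return float("nan")
    return c.P + c.Q


def kimura_k80(c: SiteCounts, min_sites: int = DEFAULT_MIN_SITES) -> float:
    """Kimura (1980) two-parameter distance in substitutions/site.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

    Returns NaN (a masked value, not an error) when the pair is
    saturated (either logarithm argument <= 0) or compared over fewer
    than ``min_sites`` sites.
    """
    if c.L < min_sites:
        return float("nan")
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a mask for undefined pairs.

    ``d`` holds NaN at masked cells; ``mask`` is True where the pair is
    unreliable (too few shared sites or K80 saturation). ``sites`` holds
    the number of compared sites per pair.
    """

    labels: list[str]
    d: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    sites: np.ndarray = field(default=None)  # type: ignore[assignment]
    model: str = "k80"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if self.mask is None:
            self.mask = np.isnan(self.d)
        if self.sites is None:
            self.sites = np.full((n, n), -1, dtype=int)
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(np.nan_to_num(self.d)), 0.0):
            raise ValueError("diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_masked(self) -> int:
        n = len(self.labels)
        off = self.mask & ~np.eye(n, dtype=bool)
        return int(off.sum()) // 2

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        ix = np.ix_(idx, idx)
        return DistanceMatrix(
            list(labels), self.d[ix], self.mask[ix], self.sites[ix], self.model
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return self.d[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def distance_matrix(
    sequences: dict[str, str] | Iterable[tuple[str, str]],
    model: str = "k80",
    min_sites: int = DEFAULT_MIN_SITES,
) -> DistanceMatrix:
    """All-pairs distance matrix under the chosen model.

    Parameters
    ----------
    sequences:
        Mapping (or iterable of pairs) label -> aligned sequence, all of
        one length.
    model:
        ``"k80"`` or ``"p"``.
    min_sites:
        Pairs sharing fewer unambiguous columns than this are masked
        (applies to both models, so masking is model-independent).
    """
    if isinstance(sequences, dict):
        items = list(sequences.items())
    else:
        items = list(sequences)
    if not items:
        raise ValueError("empty sequence set")
    if model not in ("k80", "p"):
        raise ValueError(f"unknown model: {model!r}")
    labels = [k for k, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    enc = [encode(s) for _, s in items]
    width = {e.size for e in enc}
    if len(width) != 1:
        raise ValueError("sequences are not uniformly aligned (unequal lengths)")
    n = len(labels)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = int((enc[i] != 255).sum())
        for j in range(i + 1, n):
            c = site_counts(enc[i], enc[j])
            if c.L < min_sites:
                val = float("nan")
            elif model == "k80":
                val = kimura_k80(c, min_sites=min_sites)
            else:
                val = p_distance(c)
            d[i, j] = d[j, i] = val
            sites[i, j] = sites[j, i] = c.L
    mask = np.isnan(d)
    return DistanceMatrix(labels, d, mask, sites, model)


def write_long_tsv(dm: DistanceMatrix, path: str) -> None:
    """Write the upper triangle in long format (id1, id2, model, d, L)."""
    rows = []
    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                {
                    "id1": dm.labels[i],
                    "id2": dm.labels[j],
                    "model": dm.model,
                    "d": dm.d[i, j],
                    "L": dm.sites[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_phylip(dm: DistanceMatrix, path: str) -> None:
    """Square PHYLIP distance matrix (masked cells written as -1.0)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        filled = np.where(dm.mask, -1.0, dm.d)
        for label, row in zip(dm.labels, filled):
            fh.write(label[:10].ljust(12))
            fh.write(" ".join(f"{v:.6f}" for v in row))
            fh.write("\n")
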
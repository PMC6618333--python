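"""Variable declarations and the latent-normal column layout.

A joint imputation model for a mix of continuous, binary, categorical and
count variables is built on a single multivariate-normal working matrix.
Continuous variables (and counts on a continuous working scale) occupy one
column each.  A binary variable is represented by one latent normal column
(the differenced two-latent construction, which makes the model
identifiable), decoded as 1 when the latent is positive.  A T-level
unordered categorical variable is represented by T-1 latent normal columns,
each with variance fixed to 1 and pairwise covariance within the block fixed
to 0.5; the observed level is the index of the largest positive latent, or
the reference level when all latents are negative.

The covariance matrix of the working columns is therefore only partially
free: this module records which entries are free and which are pinned to
1 or 0.5 (the ``constraint mask``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KINDS = ("continuous", "binary", "categorical", "count")
COUNT_TREATMENTS = ("untransformed", "sqrt", "log", "categorical")

#: constraint-mask codes for entries of the working covariance matrix
FREE = 0
FIXED_ONE = 1
FIXED_HALF = 2


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one observed variable.

    Parameters
    ----------
    name
        Column name in the dataset.
    kind
        One of ``continuous``, ``binary``, ``categorical``, ``count``.
    n_levels
        Number of observed levels; required (>= 3) for categorical
        variables, implicitly 2 for binary ones.
    count_treatment
        How a count variable enters the working matrix: ``untransformed``,
        ``sqrt``, ``log`` (continuous working scales) or ``categorical``
        (relabelled distinct counts imputed as an unordered categorical).
    reference_level
        Level decoded when all latents of a categorical block are negative.
        Defaults to the last level, matching the convention in which level
        ``T`` of a ``T``-level variable corresponds to an all-negative
        latent triple.
    """

    name: str
    kind: str
    n_levels: int | None = None
    count_treatment: str = "untransformed"
    reference_level: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if self.kind not in KINDS:
            raise ValueError(
                f"unknown kind {self.kind!r} for variable {self.name!r}; "
                f"expected one of {KINDS}"
            )
        if self.kind == "categorical":
            if self.n_levels is None or self.n_levels < 2:
                raise ValueError(
                    f"categorical variable {self.name!r} needs n_levels >= 3 "
                    f"(got {self.n_levels!r})"
                )
            if self.n_levels == 2:
                raise ValueError(
                    f"variable {self.name!r}: a 2-level variable must be "
                    "declared binary (coded 0/1), not categorical"
                )
            ref = self.reference_level
            if ref is None:
                object.__setattr__(self, "reference_level", self.n_levels)
            elif not 1 <= ref <= self.n_levels:
                raise ValueError(
                    f"variable {self.name!r}: reference_level {ref} outside "
                    f"1..{self.n_levels}"
                )
        elif self.kind == "binary":
            if self.n_levels not in (None, 2):
                raise ValueError(
                    f"binary variable {self.name!r} has exactly 2 levels "
                    f"(got n_levels={self.n_levels!r})"
                )
            object.__setattr__(self, "n_levels", 2)
        elif self.n_levels is not None:
            raise ValueError(
                f"variable {self.name!r} of kind {self.kind!r} does not take "
                "n_levels"
            )
        if self.kind == "count":
            if self.count_treatment not in COUNT_TREATMENTS:
                raise ValueError(
                    f"variable {self.name!r}: unknown count_treatment "
                    f"{self.count_treatment!r}; expected one of "
                    f"{COUNT_TREATMENTS}"
                )

    @property
    def n_latent_cols(self) -> int:
        """Number of working-matrix columns the variable occupies."""
        if self.kind == "categorical":
            return self.n_levels - 1
        return 1

    @property
    def is_latent(self) -> bool:
        """Whether the variable is represented by latent normal columns."""
        return self.kind in ("binary", "categorical")

    @property
    def non_reference_levels(self) -> tuple[int, ...]:
        """Levels mapped to latent columns 1..T-1, in ascending order."""
        if self.kind != "categorical":
            raise ValueError(f"{self.name!r} is not categorical")
        return tuple(
            l for l in range(1, self.n_levels + 1) if l != self.reference_level
        )


@dataclass(frozen=True)
class LatentLayout:
    """Mapping between variables and working-matrix columns.

    ``spans[k]`` is the half-open column range of variable ``k``; the spans
    partition ``0..n_cols``.  ``mask`` is the symmetric ``n_cols x n_cols``
    constraint mask over {FREE, FIXED_ONE, FIXED_HALF}.
    """

    specs: tuple[VariableSpec, ...]
    spans: tuple[tuple[int, int], ...]
    n_cols: int
    mask: np.ndarray = field(repr=False)

    def columns(self, k: int) -> np.ndarray:
        start, stop = self.spans[k]
        return np.arange(start, stop)

    def var_index(self, name: str) -> int:
        for k, s in enumerate(self.specs):
            if s.name == name:
                return k
        raise KeyError(name)

    @property
    def n_vars(self) -> int:
        return len(self.specs)

    def fixed_values(self) -> np.ndarray:
        """Matrix with the pinned values at fixed positions, NaN elsewhere."""
        out = np.full((self.n_cols, self.n_cols), np.nan)
        out[self.mask == FIXED_ONE] = 1.0
        out[self.mask == FIXED_HALF] = 0.5
        return out


def build_latent_layout(specs: list[VariableSpec]) -> LatentLayout:
    """Assign working-matrix columns and build the covariance constraint mask.

    Latent diagonals are fixed to 1; within one categorical block all
    off-diagonal entries are fixed to 0.5; every cross-variable entry (and
    the variances of continuous/count columns) is free.
    """
    if not specs:
        raise ValueError("need at least one variable spec")
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate variable names: {sorted(dupes)}")
    for s in specs:
        if s.kind == "count" and s.count_treatment == "categorical":
            raise ValueError(
                f"variable {s.name!r}: relabel count-as-categorical to a "
                "categorical spec before building the layout"
            )

    spans = []
    start = 0
    for s in specs:
        spans.append((start, start + s.n_latent_cols))
        start += s.n_latent_cols
    P = start

    mask = np.full((P, P), FREE, dtype=np.int8)
    for s, (a, b) in zip(specs, spans):
        if s.is_latent:
            mask[a:b, a:b] = FIXED_HALF
            for c in range(a, b):
                mask[c, c] = FIXED_ONE
    return LatentLayout(tuple(specs), tuple(spans), P, mask)


def decode(latent_block: np.ndarray, spec: VariableSpec) -> int:
    """Map one latent block to an observed category code.

    Binary: 1 iff z > 0.  Categorical: the level whose latent attains the
    (positive) maximum, or the reference level when no latent is positive.
    Ties and exact zeros resolve deterministically (lowest qualifying latent;
    zero counts as the non-positive branch).
    """
    block = np.asarray(latent_block, dtype=float).ravel()
    if block.shape[0] != spec.n_latent_cols:
        raise ValueError(
            f"latent block of length {block.shape[0]} does not match "
            f"variable {spec.name!r} ({spec.n_latent_cols} columns)"
        )
    if spec.kind == "binary":
        return int(block[0] > 0)
    if spec.kind != "categorical":
        raise ValueError(f"{spec.name!r} has no categorical decoding")
    j = int(np.argmax(block))
    if block[j] > 0:
        return spec.non_reference_levels[j]
    return spec.reference_level


def decode_matrix(latent_blocks: np.ndarray, spec: VariableSpec) -> np.ndarray:
    """Vectorised :func:`decode` over rows of an (N, d) block matrix."""
    Z = np.asarray(latent_blocks, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[1] != spec.n_latent_cols:
        raise ValueError(
            f"block matrix with {Z.shape[1]} columns does not match "
            f"variable {spec.name!r} ({spec.n_latent_cols} columns)"
        )
    if spec.kind == "binary":
        return (Z[:, 0] > 0).astype(np.int64)
    j = np.argmax(Z, axis=1)
    positive = Z[np.arange(Z.shape[0]), j] > 0
    levels = np.asarray(spec.non_reference_levels)[j]
    return np.where(positive, levels, spec.reference_level).astype(np.int64)


def is_consistent(
    latent_block: np.ndarray, observed_code: int, spec: VariableSpec
) -> bool:
    """Whether a latent block decodes to the observed category code."""
    code = int(observed_code)
    if spec.kind == "binary":
        valid = code in (0, 1)
    else:
        valid = 1 <= code <= (spec.n_levels or 0)
    if not valid:
        raise ValueError(
            f"code {observed_code!r} is not a valid level of {spec.name!r}"
        )
    return decode(latent_block, spec) == code
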
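"""Motion-estimator architectures: HRC, quadrant, and polynomial models.

All estimators map the filtered channel values [f1, g1, f2, g2, (f3, g3)]
at the readout time to a scalar velocity estimate.  Every architecture is
mirror-antisymmetric: reversing the spatial order of the receptors negates
the output, so leftward and rightward motion are treated equivalently.

The hierarchy nests: the Hassenstein-Reichardt correlator (HRC)

    R = (f*V1)(g*V2) - (g*V1)(f*V2)

is the equal-weight case of the weighted 4-quadrant model, which is itself
a subset of the 2-input polynomial ("non-multiplicative nonlinearity")
model, contained in turn in the 4-channel and 6-channel polynomial models.
Functions here accept arrays of shape (..., 2 * n_receptors) so they
vectorize over clips and over time.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .ensemble import Ensemble

__all__ = [
    "hrc",
    "converging_3pt",
    "quadrant_signals",
    "weighted_quadrant",
    "QuadrantWeights",
    "correlation_classes",
    "classes_to_quadrants",
    "CLASS_NAMES",
    "CLASS_MATRIX",
    "poly_exponents",
    "poly_features",
    "FrontEnd",
    "apply_front_end",
    "EstimatorModel",
    "evaluate_model",
    "predictor_matrix",
    "predictor_count",
    "ARCHITECTURES",
]

QUADRANT_ORDER = ("pp", "pm", "mp", "mm")


def _pair_channels(F: np.ndarray, pair: tuple[int, int], allow_nonadjacent: bool):
    """Extract (f_i, g_i, f_j, g_j) for a receptor pair (1-based indices)."""
    i, j = pair
    n_rec = F.shape[-1] // 2
    if not (1 <= i <= n_rec and 1 <= j <= n_rec) or i == j:
        raise ValueError(f"invalid receptor pair {pair} for {n_rec} receptors")
    if abs(i - j) != 1 and not allow_nonadjacent:
        raise ValueError(
            f"receptors {pair} are not adjacent; pass allow_nonadjacent=True "
            "for a next-nearest-neighbor correlator"
        )
    return (
        F[..., 2 * (i - 1)],
        F[..., 2 * (i - 1) + 1],
        F[..., 2 * (j - 1)],
        F[..., 2 * (j - 1) + 1],
    )


def hrc(F: np.ndarray, pair: tuple[int, int] = (1, 2), allow_nonadjacent: bool = False) -> np.ndarray:
    """Hassenstein-Reichardt correlator: f_i g_j - g_i f_j."""
    fi, gi, fj, gj = _pair_channels(np.asarray(F, float), pair, allow_nonadjacent)
    return fi * gj - gi * fj


def converging_3pt(
    F: np.ndarray,
    variant: str = "squared",
    pair: tuple[int, int] = (1, 2),
    allow_nonadjacent: bool = False,
) -> np.ndarray:
    """Mirror-antisymmetric converging 3-point correlator.

    Combines two low-pass filtered signals with one high-pass filtered
    signal.  Two conventions are implemented because the channel assignment
    of the two low-pass inputs admits both readings:

    * ``"squared"``:  f_i^2 g_j - f_j^2 g_i  (one site's low-pass squared)
    * ``"two-site"``: f_i f_j g_j - f_j f_i g_i  (low-pass product across sites)
    """
    fi, gi, fj, gj = _pair_channels(np.asarray(F, float), pair, allow_nonadjacent)
    if variant == "squared":
        return fi * fi * gj - fj * fj * gi
    if variant == "two-site":
        return fi * fj * gj - fj * fi * gi
    raise ValueError(f"unknown converging 3-point variant: {variant!r}")


def quadrant_signals(
    F: np.ndarray, pair: tuple[int, int] = (1, 2), allow_nonadjacent: bool = False
) -> np.ndarray:
    """Half-wave-rectified HRC quadrants Q_ab, stacked as (..., 4).

    Q_ab = [f_i]_a [g_j]_b - [g_i]_b [f_j]_a with a the sign of the
    low-pass channel and b the sign of the high-pass channel; order
    (++), (+-), (-+), (--).  Their sum reproduces the HRC exactly.
    """
    fi, gi, fj, gj = _pair_channels(np.asarray(F, float), pair, allow_nonadjacent)
    pos = lambda x: np.maximum(x, 0.0)
    neg = lambda x: np.minimum(x, 0.0)
    q = [
        pos(fi) * pos(gj) - pos(gi) * pos(fj),
        pos(fi) * neg(gj) - neg(gi) * pos(fj),
        neg(fi) * pos(gj) - pos(gi) * neg(fj),
        neg(fi) * neg(gj) - neg(gi) * neg(fj),
    ]
    return np.stack(q, axis=-1)


@dataclass(frozen=True)
class QuadrantWeights:
    """Weights for quadrants (++), (+-), (-+), (--); first index is the
    sign of the low-pass channel, second the sign of the high-pass channel."""

    w_pp: float = 1.0
    w_pm: float = 1.0
    w_mp: float = 1.0
    w_mm: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.w_pp, self.w_pm, self.w_mp, self.w_mm])


def weighted_quadrant(
    F: np.ndarray,
    weights: QuadrantWeights | np.ndarray,
    pair: tuple[int, int] = (1, 2),
) -> np.ndarray:
    """Weighted sum of the four rectified quadrants; equal weights = HRC."""
    w = weights.as_array() if isinstance(weights, QuadrantWeights) else np.asarray(weights, float)
    return quadrant_signals(F, pair) @ w


# Orthogonal +-1 sign patterns over (++, +-, -+, --), each scaled by 1/4.
# "even2" (the uniform row) recovers the HRC / 4; rows symmetric under the
# contrast-inversion swap (++ <-> --, +- <-> -+) pick out even-order
# correlations, antisymmetric rows pick out odd-order ones.  Which of the
# two odd rows is called "odd" vs "odd*" is a labeling convention.
CLASS_NAMES = ("even2", "odd", "odd_star", "even_gt2")
CLASS_MATRIX = 0.25 * np.array(
    [
        [1.0, 1.0, 1.0, 1.0],  # even2  (HRC)
        [1.0, 1.0, -1.0, -1.0],  # odd
        [1.0, -1.0, 1.0, -1.0],  # odd*
        [1.0, -1.0, -1.0, 1.0],  # even > 2
    ]
)


def correlation_classes(Q: np.ndarray, matrix: np.ndarray = CLASS_MATRIX) -> np.ndarray:
    """Reparameterize quadrant values into correlation classes (..., 4)."""
    return np.asarray(Q, float) @ np.asarray(matrix, float).T


def classes_to_quadrants(C: np.ndarray, matrix: np.ndarray = CLASS_MATRIX) -> np.ndarray:
    """Inverse of :func:`correlation_classes`; the map is a bijection."""
    return np.asarray(C, float) @ np.linalg.inv(np.asarray(matrix, float)).T


# ---------------------------------------------------------------------------
# polynomial feature maps


def poly_exponents(arity: int, max_order: int = 4) -> list[tuple[int, ...]]:
    """Exponent tuples of all monomials with total degree 1..max_order.

    Order is lexicographic by tuple and frozen: it defines the meaning of
    weight vectors in serialized model files.
    """
    return [
        e
        for e in itertools.product(range(max_order + 1), repeat=arity)
        if 1 <= sum(e) <= max_order
    ]


def _monomials(X: np.ndarray, exponents: list[tuple[int, ...]]) -> np.ndarray:
    """Evaluate monomial columns for channel values X of shape (..., arity)."""
    arity = X.shape[-1]
    powers = [
        [np.ones_like(X[..., c])] + [X[..., c] ** k for k in range(1, 5)] for c in range(arity)
    ]
    cols = []
    for e in exponents:
        m = powers[0][e[0]]
        for c in range(1, arity):
            if e[c]:
                m = m * powers[c][e[c]]
        cols.append(m)
    return np.stack(cols, axis=-1)


def poly_features(
    F: np.ndarray,
    arity: int,
    max_order: int = 4,
    pair: tuple[int, int] = (1, 2),
) -> np.ndarray:
    """Polynomial predictor vectors for the three nonlinearity models.

    * ``arity=2`` -- the non-multiplicative model: a bivariate polynomial of
      (low-pass from one site, high-pass from its neighbor), explicitly
      antisymmetrized over the mirror pair:
      x^i y^j with (x, y) = (f_i, g_j) minus the same monomial with
      (x, y) = (f_j, g_i).  14 features at fourth order.
    * ``arity=4`` -- all monomials of (f1, g1, f2, g2): 69 features.
    * ``arity=6`` -- all monomials of the six channels of two neighboring
      detectors: 209 features.
    """
    F = np.asarray(F, float)
    n_channels = F.shape[-1]
    exps = None
    if arity == 2:
        fi, gi, fj, gj = _pair_channels(F, pair, allow_nonadjacent=False)
        exps = poly_exponents(2, max_order)
        fwd = _monomials(np.stack([fi, gj], axis=-1), exps)
        rev = _monomials(np.stack([fj, gi], axis=-1), exps)
        return fwd - rev
    if arity in (4, 6):
        if n_channels < arity:
            raise ValueError(f"arity {arity} needs {arity} channels, bank has {n_channels}")
        exps = poly_exponents(arity, max_order)
        return _monomials(F[..., :arity], exps)
    raise ValueError(f"arity must be 2, 4, or 6; got {arity}")


# ---------------------------------------------------------------------------
# front-end nonlinearities


@dataclass
class FrontEnd:
    """Static monotone transform applied to photoreceptor outputs.

    Kinds:

    * ``"gaussianize"`` -- ranks scaled to (0, 1), mapped through the inverse
      Gaussian CDF; output marginal is Gaussian (kurtosis 3).
    * ``"equalize"`` -- ranks scaled and shifted to span [-1, +1]; output
      marginal is uniform (kurtosis 1.8).
    * ``"binarize"`` -- percentile thresholds split the pooled values into
      alternating -1 / +1 bands.  A single 50th-percentile threshold is the
      median binarization (symmetric Bernoulli output, kurtosis 1); the
      (25, 75) variant maps the outer quartiles to -1 and the inner half
      to +1.  Binary outputs have the lowest kurtosis any distribution
      can attain.

    The paper-style usage pools every value (all receptors, times, and
    motions) into one rank transform; :meth:`fit` + :meth:`apply` instead
    freeze the lookup on a training pool and interpolate new data through
    it, for leakage-free evaluation.  Ties share their mean rank.
    """

    kind: str = "equalize"
    thresholds: tuple[float, ...] = (50.0,)
    _lookup_x: np.ndarray | None = field(default=None, repr=False)
    _lookup_y: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in {"gaussianize", "equalize", "binarize"}:
            raise ValueError(f"unknown front-end kind: {self.kind!r}")

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Pooled transform: rank every value in ``values`` jointly."""
        x = np.asarray(values, dtype=float)
        flat = x.ravel()
        if flat.size == 0:
            raise ValueError("empty pool")
        if self.kind == "binarize":
            cuts = np.percentile(flat, sorted(self.thresholds))
            band = np.searchsorted(cuts, flat, side="left")
            out = np.where(band % 2 == 1, 1.0, -1.0)
        else:
            r = rankdata(flat, method="average")
            if self.kind == "equalize":
                out = 2.0 * (r - 1.0) / (flat.size - 1.0) - 1.0
            else:  # gaussianize
                out = ndtri(r / (flat.size + 1.0))
        return out.reshape(x.shape)

    def fit(self, pool: np.ndarray) -> "FrontEnd":
        """Freeze a monotone lookup on a training pool."""
        pool = np.sort(np.asarray(pool, dtype=float).ravel())
        if pool.size == 0:
            raise ValueError("empty pool")
        self._lookup_x = pool
        self._lookup_y = self.transform(pool)
        return self

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Map new data through the frozen lookup by interpolation."""
        if self._lookup_x is None:
            raise ValueError("front end not fitted; call fit() or use transform()")
        x = np.asarray(values, dtype=float)
        out = np.interp(x.ravel(), self._lookup_x, self._lookup_y)
        return out.reshape(x.shape)


def apply_front_end(ens: Ensemble, fe: FrontEnd) -> Ensemble:
    """Transform an ensemble's photoreceptor signals with a pooled front end.

    All values -- every receptor, time point, and motion -- are ranked
    together, matching how the transform reshapes the full input marginal.
    """
    return ens.with_values(fe.transform(ens.V).reshape(ens.V.shape))


# ---------------------------------------------------------------------------
# uniform model interface


def _arch_hrc(F, opts):
    return hrc(F, pair=tuple(opts.get("pair", (1, 2))))[..., np.newaxis]


def _arch_conv3(F, opts):
    return converging_3pt(
        F,
        variant=opts.get("variant", "squared"),
        pair=tuple(opts.get("pair", (1, 2))),
        allow_nonadjacent=bool(opts.get("allow_nonadjacent", False)),
    )[..., np.newaxis]


def _arch_hrc_conv3(F, opts):
    return np.concatenate([_arch_hrc(F, opts), _arch_conv3(F, opts)], axis=-1)


def _arch_quadrant(F, opts):
    return quadrant_signals(F, pair=tuple(opts.get("pair", (1, 2))))


def _arch_poly(arity):
    def build(F, opts):
        return poly_features(F, arity=arity, pair=tuple(opts.get("pair", (1, 2))))

    return build


#: architecture tag -> (predictor builder, predictor count)
ARCHITECTURES: dict = {
    "hrc": (_arch_hrc, 1),
    "conv3": (_arch_conv3, 1),
    "hrc+conv3": (_arch_hrc_conv3, 2),
    "quadrant": (_arch_quadrant, 4),
    "poly2": (_arch_poly(2), 14),
    "poly4": (_arch_poly(4), 69),
    "poly6": (_arch_poly(6), 209),
}


def predictor_matrix(architecture: str, F: np.ndarray, **options) -> np.ndarray:
    """Predictor vectors (..., n_predictors) for a named architecture."""
    try:
        build, _ = ARCHITECTURES[architecture]
    except KeyError:
        raise ValueError(f"unknown architecture: {architecture!r}") from None
    return build(np.asarray(F, float), options)


def predictor_count(architecture: str) -> int:
    return ARCHITECTURES[architecture][1]


@dataclass
class EstimatorModel:
    """A named architecture with fitted weights and an output scale.

    ``evaluate`` returns scale * (predictors @ weights); the scale is the
    optimal output gain r * sigma_v / sigma_R fixed at fit time.  For
    polynomial architectures the exponent table implied by the weight
    ordering is serialized alongside the weights so files are
    self-describing and round-trip exactly.
    """

    architecture: str
    weights: np.ndarray | None = None
    scale: float = 1.0
    options: dict = field(default_factory=dict)

    def n_predictors(self) -> int:
        return predictor_count(self.architecture)

    def features(self, F: np.ndarray) -> np.ndarray:
        return predictor_matrix(self.architecture, F, **self.options)

    def evaluate(self, F: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise ValueError("model weights are unset; fit or assign them first")
        w = np.asarray(self.weights, float)
        if w.size != self.n_predictors():
            raise ValueError(
                f"{self.architecture} expects {self.n_predictors()} weights, got {w.size}"
            )
        return self.scale * (self.features(F) @ w)

    def to_dict(self) -> dict:
        d = {
            "architecture": self.architecture,
            "weights": None if self.weights is None else np.asarray(self.weights).tolist(),
            "scale": self.scale,
            "options": self.options,
        }
        if self.architecture in {"poly2", "poly4", "poly6"}:
            arity = int(self.architecture[-1])
            d["exponents"] = [list(e) for e in poly_exponents(arity)]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EstimatorModel":
        w = d.get("weights")
        return cls(
            architecture=d["architecture"],
            weights=None if w is None else np.asarray(w, float),
            scale=float(d.get("scale", 1.0)),
            options=dict(d.get("options", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EstimatorModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def evaluate_model(model: EstimatorModel, F: np.ndarray) -> np.ndarray:
    """Scalar estimate(s) of a fitted model on channel values (..., 2R)."""
    return model.evaluate(F)
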
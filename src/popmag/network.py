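"""Layer-wise activation-magnitude analysis for feedforward networks.

For each hidden layer of a feedforward network, the response magnitude
of an image is the L2 norm of the layer's full post-nonlinearity output
vector. Per layer, the Pearson correlation between per-image magnitudes
and memorability scores is estimated with a percentile bootstrap over
images (resample image indices with replacement, recompute r), with
resampling independent per layer and per condition. Two conditions
(e.g. a task-trained network vs the same architecture randomly
initialized) are compared one-sidedly by the rate at which the second
condition's bootstrap r meets or exceeds the first's.

Real networks plug in through the forward-pass contract: any object
with ``layer_names`` and a ``forward(x)`` returning the post-
nonlinearity output vector of each hidden layer in hierarchy order.
The bundled :class:`ToyFeedforwardNet` exists to exercise that contract
with a small, dependency-free architecture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from popmag._streams import stream

__all__ = [
    "ForwardPassContract",
    "ToyFeedforwardNet",
    "BootstrapResult",
    "layer_magnitudes",
    "layer_correlation_profile",
    "trained_vs_random_test",
]


@runtime_checkable
class ForwardPassContract(Protocol):
    """Adapter contract for any feedforward network."""

    @property
    def layer_names(self) -> list[str]: ...

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Post-nonlinearity output vector of each hidden layer, in order."""
        ...


class ToyFeedforwardNet:
    """A small ReLU network: three conv-like stages and two fully
    connected layers, with fan-in-scaled random weights.

    ``scale`` rescales all weights; a scale of 0 with zero biases maps
    every input to zero activations, which is occasionally useful in
    tests. Weights are drawn once at construction from the given seed
    (He-style sqrt(2/fan_in) standard deviation), so two nets built from
    the same seed are identical.
    """

    def __init__(
        self,
        input_dim: int = 192,
        layer_dims: Sequence[int] = (96, 64, 48, 32, 16),
        seed: int = 0,
        scale: float = 1.0,
    ):
        rng = stream(seed, "toy_net")
        self._weights = []
        self._biases = []
        fan_in = input_dim
        for dim in layer_dims:
            w = rng.standard_normal((dim, fan_in)) * np.sqrt(2.0 / fan_in) * scale
            self._weights.append(w)
            self._biases.append(np.zeros(dim))
            fan_in = dim
        n_conv = min(3, len(layer_dims))
        self._names = [f"conv{i + 1}" for i in range(n_conv)] + [
            f"fc{i + 1}" for i in range(len(layer_dims) - n_conv)
        ]
        self.input_dim = input_dim

    @property
    def layer_names(self) -> list[str]:
        return list(self._names)

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        h = np.asarray(x, dtype=float).ravel()
        if h.size != self.input_dim:
            raise ValueError(f"expected input of size {self.input_dim}, got {h.size}")
        outputs = []
        for w, b in zip(self._weights, self._biases):
            h = np.maximum(0.0, w @ h + b)
            outputs.append(h)
        return outputs


def layer_magnitudes(adapter: ForwardPassContract, images) -> pd.DataFrame:
    """Per-image, per-layer L2 magnitudes of hidden-layer outputs.

    ``images`` is an iterable of (preprocessed) input tensors; each is
    passed through the adapter and every layer's full output vector is
    reduced to its L2 norm. Returns a DataFrame with one row per image
    and one column per layer, in hierarchy order.
    """
    names = adapter.layer_names
    rows = []
    for i, image in enumerate(images):
        outputs = adapter.forward(image)
        if len(outputs) != len(names):
            raise ValueError("adapter returned a different number of layers")
        mags = []
        for vec in outputs:
            vec = np.asarray(vec, dtype=float).ravel()
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite activations at image {i}")
            mags.append(float(np.linalg.norm(vec)))
        rows.append(mags)
    return pd.DataFrame(rows, columns=names)


@dataclass
class BootstrapResult:
    """Bootstrap of per-layer magnitude-memorability correlations."""

    layer_names: list[str]
    #: Plug-in Pearson r per layer (NaN where magnitudes are degenerate).
    r: np.ndarray
    #: Mean of the bootstrap replicates per layer.
    r_boot_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    #: (n_replicates, n_layers) bootstrap replicates.
    replicates: np.ndarray
    n_replicates: int
    seed: int

    def __post_init__(self):
        ok = ~np.isnan(self.r)
        if np.any(self.ci_low[ok] > self.r[ok] + 1e-12) or np.any(
            self.r[ok] > self.ci_high[ok] + 1e-12
        ):
            raise ValueError("CI must bracket the point estimate")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer": self.layer_names,
                "r": self.r,
                "r_boot_mean": self.r_boot_mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between matching rows of x and y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def layer_correlation_profile(
    magnitudes,
    memorability,
    n_replicates: int = 10_000,
    seed: int = 0,
    condition: str = "",
    chunk: int = 256,
) -> BootstrapResult:
    """Per-layer Pearson r with percentile-bootstrap 95% CIs.

    ``magnitudes`` is (n_images, n_layers) (array or DataFrame);
    resampling of image indices is independent per layer. The CI
    endpoints are the empirical 2.5 and 97.5 centiles of the replicates.
    A layer with zero-variance magnitudes yields NaN estimates (with a
    warning) rather than an error.
    """
    if isinstance(magnitudes, pd.DataFrame):
        layer_names = list(magnitudes.columns)
        mags = magnitudes.to_numpy(dtype=float)
    else:
        mags = np.asarray(magnitudes, dtype=float)
        layer_names = [f"layer{i + 1}" for i in range(mags.shape[1])]
    m = np.asarray(memorability, dtype=float)
    n_images, n_layers = mags.shape
    if len(m) != n_images:
        raise ValueError("memorability length must match the number of images")
    if n_images < 3:
        raise ValueError("need at least 3 images")

    r = np.full(n_layers, np.nan)
    replicates = np.full((n_replicates, n_layers), np.nan)
    for l in range(n_layers):
        x = mags[:, l]
        if np.std(x) == 0 or np.std(m) == 0:
            warnings.warn(
                f"zero-variance magnitudes in layer {layer_names[l]}; "
                "r reported missing",
                stacklevel=2,
            )
            continue
        r[l] = _pearson_rows(x[None, :], m[None, :])[0]
        rng = stream(seed, "bootstrap", condition, l)
        done = 0
        while done < n_replicates:
            size = min(chunk, n_replicates - done)
            idx = rng.integers(0, n_images, size=(size, n_images))
            replicates[done : done + size, l] = _pearson_rows(x[idx], m[idx])
            done += size

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN degenerate layers
        ci_low = np.nanpercentile(replicates, 2.5, axis=0)
        ci_high = np.nanpercentile(replicates, 97.5, axis=0)
        boot_mean = np.nanmean(replicates, axis=0)
    bad = np.isnan(r)
    ci_low[bad] = np.nan
    ci_high[bad] = np.nan
    boot_mean[bad] = np.nan
    return BootstrapResult(
        layer_names=layer_names,
        r=r,
        r_boot_mean=boot_mean,
        ci_low=ci_low,
        ci_high=ci_high,
        replicates=replicates,
        n_replicates=n_replicates,
        seed=seed,
    )


def trained_vs_random_test(
    trained: BootstrapResult | np.ndarray, random: BootstrapResult | np.ndarray
) -> np.ndarray:
    """One-sided per-layer p: rate at which the random condition's
    bootstrap r meets or exceeds the trained condition's.

    Replicates are paired by index; ties count toward the exceedance
    numerator (conservative). The reported p is floored at
    1/n_replicates, the resolution of the bootstrap.
    """
    a = trained.replicates if isinstance(trained, BootstrapResult) else np.asarray(trained)
    b = random.replicates if isinstance(random, BootstrapResult) else np.asarray(random)
    a = np.atleast_2d(a.astype(float))
    b = np.atleast_2d(b.astype(float))
    if a.shape != b.shape:
        raise ValueError(
            f"replicate arrays must match: {a.shape} vs {b.shape} "
            "(same resampling scheme required)"
        )
    n = a.shape[0]
    p = (b >= a).mean(axis=0)
    return np.maximum(p, 1.0 / n)
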
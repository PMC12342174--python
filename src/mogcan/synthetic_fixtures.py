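"""Seeded synthetic multi-omics generators with known subtype structure.

Two entry points: :func:`generate` builds configurable multi-view Gaussian
(or log-normal) datasets with class-dependent mean shifts, per-view noise,
missing values and class imbalance; :func:`make_toy_worked_example`
returns a fixed 6-sample two-view dataset used as a hand-checkable
reference throughout the test suite.

With ``complementary=True`` each view can only separate the class
contrasts assigned to it (view ``u`` shifts the mean only for classes
``c`` with ``(c - 1) % n_omics == u``; all other classes share the
baseline mean), so no single view separates all classes but the union of
views does — the construction under which fusing views must beat any
single view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import LabelTable, OmicsMatrix

__all__ = ["SyntheticConfig", "generate", "make_toy_worked_example"]


@dataclass
class SyntheticConfig:
    n_samples: int = 150
    n_classes: int = 3
    class_proportions: list[float] | None = None
    n_omics: int = 2
    features_per_omics: list[int] = field(default_factory=lambda: [60, 60])
    informative_fraction: float = 0.5
    effect_size: float = 5.0      # class-mean shift in noise-SD units
    noise_sd: float = 1.0
    na_fraction: float = 0.0
    complementary: bool = False
    feature_model: str = "gaussian"   # or "lognormal" (heavy-tailed)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            self.class_proportions = [1.0 / self.n_classes] * self.n_classes
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != self.n_classes or (props <= 0).any() \
                or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError(
                "class_proportions must be a positive vector of length "
                "n_classes summing to 1")
        if len(self.features_per_omics) != self.n_omics:
            raise ValueError("features_per_omics length must equal n_omics")
        if not 0.0 < self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must be in (0, 1]")
        if not 0.0 <= self.na_fraction < 1.0:
            raise ValueError("na_fraction must be in [0, 1)")
        if self.feature_model not in ("gaussian", "lognormal"):
            raise ValueError("feature_model must be gaussian or lognormal")


def _class_group(c: int, u: int, n_omics: int, complementary: bool) -> int:
    """Class index view ``u`` can actually see for class ``c``."""
    if not complementary:
        return c
    if c >= 1 and (c - 1) % n_omics == u:
        return c
    return 0  # merged baseline group


def generate(config: SyntheticConfig
             ) -> tuple[list[OmicsMatrix], LabelTable, dict]:
    """Draw a seeded multi-view dataset.

    Returns the omics views (with NaN missing markers when
    ``na_fraction > 0``), the label table, and a ground-truth record with
    the class assignment and informative-feature bookkeeping.
    """
    rng = np.random.default_rng(config.seed)
    n, C = config.n_samples, config.n_classes
    y = rng.choice(C, size=n, p=config.class_proportions)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    shift = config.effect_size * config.noise_sd
    omics: list[OmicsMatrix] = []
    truth: dict = {"labels": y.copy(), "informative": {}, "patterns": {}}
    for u in range(config.n_omics):
        d = config.features_per_omics[u]
        n_inf = max(1, int(round(config.informative_fraction * d)))
        # sign pattern per visible class group; group 0 is the baseline
        pattern = rng.choice([-1.0, 1.0], size=(C, n_inf))
        pattern[0] = 0.0
        X = rng.normal(0.0, config.noise_sd, size=(n, d))
        groups = np.array([_class_group(c, u, config.n_omics,
                                        config.complementary) for c in y])
        X[:, :n_inf] += shift * pattern[groups]
        if config.feature_model == "lognormal":
            X = np.exp(X / max(1.0, abs(X).max() / 4.0))  # bounded exponent
        if config.na_fraction > 0:
            na = rng.random(X.shape) < config.na_fraction
            X[na] = np.nan
        name = f"omics{u}"
        omics.append(OmicsMatrix(
            sample_ids=list(sample_ids),
            feature_names=[f"{name}_f{j}" for j in range(d)],
            values=X, name=name))
        truth["informative"][name] = list(range(n_inf))
        truth["patterns"][name] = pattern

    labels = LabelTable(sample_ids=list(sample_ids),
                        labels=[f"subtype{c}" for c in y])
    return omics, labels, truth


# Fixed 6-sample, 2-view toy dataset. Values are small integers so kernel
# and fusion intermediates can be recomputed by hand; the frozen reference
# tables live in the test suite.
_TOY_IDS = ["P1", "P2", "P3", "P4", "P5", "P6"]
_TOY_X1 = np.array([
    [0.0, 0.0],
    [0.5, 0.0],
    [0.0, 0.5],
    [3.0, 3.0],
    [3.5, 3.0],
    [3.0, 3.5],
])
_TOY_X2 = np.array([
    [1.0, 0.0, 0.0],
    [1.0, 0.5, 0.0],
    [4.0, 0.0, 1.0],
    [4.0, 0.5, 1.0],
    [1.0, 0.0, 4.0],
    [1.0, 0.5, 4.0],
])
_TOY_LABELS = ["a", "a", "b", "b", "a", "b"]


def make_toy_worked_example() -> tuple[list[OmicsMatrix], LabelTable]:
    """Hard-coded 6-sample, 2-omics dataset with hand-checkable values."""
    omics = [
        OmicsMatrix(sample_ids=list(_TOY_IDS),
                    feature_names=["f0", "f1"],
                    values=_TOY_X1.copy(), name="toy1"),
        OmicsMatrix(sample_ids=list(_TOY_IDS),
                    feature_names=["g0", "g1", "g2"],
                    values=_TOY_X2.copy(), name="toy2"),
    ]
    labels = LabelTable(sample_ids=list(_TOY_IDS), labels=list(_TOY_LABELS))
    return omics, labels
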
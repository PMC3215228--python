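"""Synthetic statistical cohorts calibrated to published summary statistics.

A cohort is drawn per sex from a multivariate normal over the meniscus
measures, body height and weight, with the published means, SDs and
within-sex Pearson correlations.  Correlations that were never published are
completed with zero; the assembled matrix is projected to the nearest
positive semi-definite correlation matrix (eigenvalue clipping at zero, then
diagonal rescaling to one) and the draw is truncated at physical bounds
(areas, volumes, thickness and width positive; percentages within
[0, 100]).  Two columns are derived rather than drawn:

* the normalized meniscus size ``TOTA_over_ACdAB = TOT_A / ACdAB`` — its
  mean, SD and reduced coefficient of variation therefore *emerge* from the
  joint distribution of TOT A and plateau area instead of being imposed;
* the three surface components TA/FA/EA are rescaled per subject to sum
  exactly to the drawn TOT A, preserving the ``TOT_A = TA + FA + EA``
  identity of the measurement pipeline.

Sampling is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import BODY, N_SUBJECTS, REFERENCE
from .segio import ValidationError

__all__ = ["CohortConfig", "cohort_config", "sample_cohort", "nearest_psd_correlation"]

#: physical truncation bounds per variable
_DEFAULT_BOUNDS = {
    "ACdAB": (1e-6, None), "V": (1e-6, None), "TA": (1e-6, None),
    "FA": (1e-6, None), "EA": (1e-6, None), "TOT_A": (1e-6, None),
    "Th_Me": (1e-6, None), "Th_Max": (1e-6, None),
    "Wid_Me": (1e-6, None), "Wid_Max": (1e-6, None),
    "TA_Uncovp": (0.0, 100.0), "ACdAB_Covp": (0.0, 100.0),
    "height": (1e-6, None), "weight": (1e-6, None),
}

_SAMPLED_VARIABLES = (
    "ACdAB", "V", "TA", "FA", "EA", "TOT_A", "Th_Me", "Th_Max", "Wid_Me",
    "Wid_Max", "TA_Uncovp", "Ex_Me", "Ex_Max", "ACdAB_Covp", "OvD_Me",
    "OvD_Max", "height", "weight",
)

# Correlations tying the drawn surface components to the drawn TOT A (and to
# each other).  They were not published; high values keep the per-subject
# rescale factor TOT_A / (TA + FA + EA) close to one so the component means
# and SDs stay near their configured values.
_COMPONENT_TOT_R = 0.95
_COMPONENT_PAIR_R = 0.88


@dataclass
class CohortConfig:
    """Per-sex calibration of a synthetic cohort for one compartment."""

    compartment: str
    variables: tuple[str, ...]
    n: dict[str, int]
    means: dict[str, dict[str, float]]          # sex -> var -> mean
    sds: dict[str, dict[str, float]]
    corr: dict[str, dict[tuple[str, str], float]]   # sex -> (v1, v2) -> r
    bounds: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    age_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {s: BODY[s]["age_range"] for s in ("M", "F")})
    seed: int = 0

    def __post_init__(self) -> None:
        for sex in ("M", "F"):
            if self.n[sex] < 2:
                raise ValidationError("need at least 2 subjects per sex")
            for v in self.variables:
                if self.sds[sex][v] < 0:
                    raise ValidationError(f"SD of {v} must be >= 0")
            for pair, r in self.corr[sex].items():
                if not -1.0 <= r <= 1.0:
                    raise ValidationError(f"correlation {pair} out of [-1, 1]: {r}")


def cohort_config(compartment: str, n_men: int | None = None,
                  n_women: int | None = None, seed: int = 0) -> CohortConfig:
    """Configuration calibrated to the published reference statistics."""
    ref = REFERENCE[compartment]
    n = {"M": n_men if n_men is not None else N_SUBJECTS["M"],
         "F": n_women if n_women is not None else N_SUBJECTS["F"]}
    means, sds, corr = {}, {}, {}
    for k, sex in enumerate(("M", "F")):
        means[sex] = {v: ref[sex][v][0] for v in _SAMPLED_VARIABLES if v in ref[sex]}
        sds[sex] = {v: ref[sex][v][1] for v in _SAMPLED_VARIABLES if v in ref[sex]}
        means[sex]["height"], sds[sex]["height"] = BODY[sex]["height"]
        means[sex]["weight"], sds[sex]["weight"] = BODY[sex]["weight"]
        corr[sex] = {pair: rs[k] for pair, rs in ref["corr"].items()}
        for comp in ("TA", "FA", "EA"):
            corr[sex][(comp, "TOT_A")] = _COMPONENT_TOT_R
            # keep the block consistent: a component tracking TOT A at 0.95
            # must echo TOT A's published correlations with the other
            # variables, else the matrix is far from positive semi-definite
            # and the repair would distort the published entries
            for (v1, v2), rs in ref["corr"].items():
                other = v2 if v1 == "TOT_A" else v1 if v2 == "TOT_A" else None
                if other is not None:
                    corr[sex][(comp, other)] = _COMPONENT_TOT_R * rs[k]
        corr[sex][("TA", "FA")] = _COMPONENT_PAIR_R
        corr[sex][("TA", "EA")] = _COMPONENT_PAIR_R
        corr[sex][("FA", "EA")] = _COMPONENT_PAIR_R
    return CohortConfig(compartment=compartment, variables=_SAMPLED_VARIABLES,
                        n=n, means=means, sds=sds, corr=corr, seed=seed)


def nearest_psd_correlation(c: np.ndarray) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at zero and the diagonal rescaled to one.
    Returns the repaired matrix and the largest absolute entry change.
    """
    c = np.asarray(c, dtype=float)
    c = 0.5 * (c + c.T)
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= 0:
        return c, 0.0
    fixed = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, float(np.abs(fixed - c).max())


def _build_corr_matrix(variables, entries) -> np.ndarray:
    idx = {v: i for i, v in enumerate(variables)}
    c = np.eye(len(variables))
    for (v1, v2), r in entries.items():
        if v1 in idx and v2 in idx:
            c[idx[v1], idx[v2]] = c[idx[v2], idx[v1]] = r
    return c


def sample_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort; returns one row per subject with sex M/F and all measures.

    ``df.attrs`` records the compartment, the seed, the maximum correlation
    adjustment made by the PSD repair per sex, and the number of values
    truncated at the physical bounds.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    attrs = {"compartment": config.compartment, "psd_adjustment": {},
             "n_truncated": {}}
    for sex in ("M", "F"):
        varnames = list(config.variables)
        mean = np.array([config.means[sex][v] for v in varnames])
        sd = np.array([config.sds[sex][v] for v in varnames])
        c, delta = nearest_psd_correlation(_build_corr_matrix(varnames, config.corr[sex]))
        attrs["psd_adjustment"][sex] = delta
        vals, vecs = np.linalg.eigh(c)
        a = vecs * np.sqrt(np.clip(vals, 0.0, None))
        z = rng.standard_normal((config.n[sex], len(varnames)))
        x = mean + (z @ a.T) * sd

        n_trunc = 0
        for j, v in enumerate(varnames):
            lo, hi = config.bounds.get(v, (None, None))
            col = x[:, j]
            bad = np.zeros(len(col), dtype=bool)
            if lo is not None:
                bad |= col < lo
            if hi is not None:
                bad |= col > hi
            n_trunc += int(bad.sum())
            x[:, j] = np.clip(col, lo if lo is not None else -np.inf,
                              hi if hi is not None else np.inf)
        attrs["n_truncated"][sex] = n_trunc

        df = pd.DataFrame(x, columns=varnames)
        # derive: components rescaled to sum to TOT A; normalized size ratio
        if {"TA", "FA", "EA", "TOT_A"} <= set(varnames):
            s = df["TOT_A"] / (df["TA"] + df["FA"] + df["EA"])
            for comp in ("TA", "FA", "EA"):
                df[comp] *= s
        if {"TOT_A", "ACdAB"} <= set(varnames):
            df["TOTA_over_ACdAB"] = df["TOT_A"] / df["ACdAB"]
        lo, hi = config.age_range[sex]
        df.insert(0, "age", rng.integers(lo, hi + 1, size=config.n[sex]))
        df.insert(0, "sex", sex)
        df.insert(0, "compartment", config.compartment)
        df.insert(0, "subject_id", [f"{sex}{i:03d}" for i in range(config.n[sex])])
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs.update(attrs)
    return out
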
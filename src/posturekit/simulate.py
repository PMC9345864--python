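"""Synthetic sessions and cohorts.

Two generators make the whole pipeline testable without patient data:

* :func:`make_posture` inverts the feature definitions -- given target
  values for F1..F5 and F7 it constructs frontal- and lateral-view
  landmark frames whose noise-free feature extraction recovers the targets
  exactly, optionally jittered by isotropic Gaussian landmark noise
  emulating depth-camera tracking error.

* :func:`simulate_cohort` draws per-subject feature vectors from group
  distributions whose defaults are the published clinical-study group
  summaries (healthy controls, PD without postural abnormalities, PD with
  postural abnormalities, and the pooled all-PD marginal).  Within each
  group, features follow a one-factor equicorrelated Gaussian, censored at
  zero; the underlying means are compensated so the censored marginal
  means match the group means exactly, and the common correlation is
  identified in closed form from the group's summary-index SD.  See
  docs/methods.md for why censoring (not conditional truncation) and why
  the correlation cannot be taken as zero.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .features import FEATURE_NAMES, compute_features
from .index import DEFAULT_WEIGHTS, IPAWeights, compute_ipa
from .session import LANDMARKS, LandmarkFrame, Session
from .stats import GroupComparison, binormal_auc, compare_groups, roc_youden

#: Frames per 5-s protocol window at the depth camera's 30 fps.
FRAMES_PER_WINDOW = 150
FPS = 30.0

#: Default landmark jitter SD (metres), approximating depth-camera noise.
DEFAULT_NOISE_SD = 0.005

#: FC may sit at most this multiple of the trunk length from L5.
MAX_FC_REACH = 2.0

# Published group summaries (mean, SD) per feature; F1..F5 degrees, F7 percent.
TABLE1_FEATURE_MEANS = {
    "HC": {"F1": 1.9, "F2": 0.3, "F3": 10.5, "F4": 7.0, "F5": 3.1, "F7": 12.5},
    "PwtPA": {"F1": 4.5, "F2": 1.0, "F3": 33.8, "F4": 21.2, "F5": 10.2, "F7": 22.4},
    "PwPA": {"F1": 10.9, "F2": 2.9, "F3": 45.1, "F4": 26.8, "F5": 14.1, "F7": 28.9},
    "PD": {"F1": 7.8, "F2": 2.0, "F3": 39.6, "F4": 24.0, "F5": 12.2, "F7": 25.7},
}
TABLE1_FEATURE_SDS = {
    "HC": {"F1": 1.7, "F2": 0.6, "F3": 4.2, "F4": 3.6, "F5": 2.6, "F7": 2.9},
    "PwtPA": {"F1": 4.5, "F2": 1.0, "F3": 9.7, "F4": 4.7, "F5": 4.9, "F7": 4.3},
    "PwPA": {"F1": 6.9, "F2": 2.4, "F3": 14.0, "F4": 10.0, "F5": 10.2, "F7": 10.2},
    "PD": {"F1": 6.6, "F2": 2.1, "F3": 13.2, "F4": 8.3, "F5": 8.2, "F7": 8.5},
}
#: Published per-group SDs of the summary index itself.
TABLE1_IPA_SDS = {"HC": 1.6, "PwtPA": 3.5, "PwPA": 7.3, "PD": 6.6}
TABLE1_SIZES = {"HC": 30, "PwtPA": 34, "PwPA": 36, "PD": 70}


# ---------------------------------------------------------------------------
# geometric forward construction


@dataclass(frozen=True)
class FeatureTargets:
    """Feature values a synthetic skeleton should realize, plus anthropometry.

    Angles in degrees (F1-F3 in [0, 90), F4/F5 in [0, 90]), F7 in percent.
    Lengths in metres: trunk C7-L5, leg L5-LM, head MH-C7.
    """

    f1: float = 0.0
    f2: float = 0.0
    f3: float = 0.0
    f4: float = 0.0
    f5: float = 0.0
    f7: float = 0.0
    trunk_length: float = 0.50
    leg_length: float = 0.80
    head_offset: float = 0.25

    def __post_init__(self):
        for name, hi in (("f1", 90.0), ("f2", 90.0), ("f3", 90.0)):
            v = getattr(self, name)
            if not 0.0 <= v < hi:
                raise ValueError(f"{name.upper()} must be in [0, {hi:g}), got {v}")
        for name in ("f4", "f5"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name.upper()} must be in [0, 90], got {v}")
        if self.f7 < 0.0:
            raise ValueError(f"F7 must be >= 0, got {self.f7}")
        for name in ("trunk_length", "leg_length", "head_offset"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_features(cls, values, **anthropometry) -> "FeatureTargets":
        f1, f2, f3, f4, f5, f7 = (float(v) for v in values)
        return cls(f1=f1, f2=f2, f3=f3, f4=f4, f5=f5, f7=f7, **anthropometry)


def _unit(angle_deg: float) -> np.ndarray:
    """In-plane unit vector at ``angle_deg`` from vertical (u, v components)."""
    a = np.radians(angle_deg)
    return np.array([np.sin(a), np.cos(a)])


def _lateral_layout(t: FeatureTargets) -> dict[str, np.ndarray]:
    """Sagittal-plane (u, v) landmark positions realizing F3, F4, F5, F7."""
    lm = np.array([0.0, 0.0])
    l5 = np.array([0.0, t.leg_length])
    c7 = l5 + t.trunk_length * _unit(t.f4)
    if t.f7 == 0.0:
        if t.f5 != t.f4:
            raise ValueError(
                "unsatisfiable targets: F7 = 0 forces FC onto the C7-L5 chord, "
                "which requires F5 == F4"
            )
        fc = l5 + 0.5 * (c7 - l5)
    else:
        sin_sep = abs(np.sin(np.radians(t.f4 - t.f5)))
        if sin_sep == 0.0:
            raise ValueError(
                "unsatisfiable targets: F7 > 0 requires F5 != F4 "
                "(FC off the C7-L5 chord)"
            )
        reach = (t.f7 / 100.0) * t.trunk_length / sin_sep
        if reach > MAX_FC_REACH * t.trunk_length:
            raise ValueError(
                f"unsatisfiable targets: F7 = {t.f7:g} with |F4 - F5| = "
                f"{abs(t.f4 - t.f5):g} deg places FC {reach:.3f} m from L5, beyond "
                f"the anatomical bound of {MAX_FC_REACH:g} trunk lengths"
            )
        fc = l5 + reach * _unit(t.f5)
    mh = c7 + t.head_offset * _unit(t.f3)
    mn = c7 + 0.5 * (mh - c7)  # on the C7-MH segment
    return {"MH": mh, "MN": mn, "C7": c7, "L5": l5, "FC": fc, "LM": lm}


def _frontal_layout(t: FeatureTargets) -> dict[str, np.ndarray]:
    """Coronal-plane (u, v) landmark positions realizing F1 and F2."""
    lm = np.array([0.0, 0.0])
    l5 = np.array([0.0, t.leg_length])  # vertical leg
    c7 = l5 + t.trunk_length * _unit(t.f2)
    mh = c7 + t.head_offset * _unit(t.f1)
    mn = c7 + 0.5 * (mh - c7)
    fc = l5 + 0.5 * (c7 - l5)  # unused by coronal features
    return {"MH": mh, "MN": mn, "C7": c7, "L5": l5, "FC": fc, "LM": lm}


def _embed(layout: dict[str, np.ndarray], view: str, depth: float = 2.0):
    """Lift in-plane (u, v) coordinates to camera-frame 3D points."""
    out = {}
    for name, (u, v) in layout.items():
        if view == "frontal":  # coronal plane: u -> X
            out[name] = np.array([u, v, depth])
        else:  # sagittal plane: u -> Z
            out[name] = np.array([0.0, v, depth + u])
    return out


def make_posture(
    targets: FeatureTargets,
    noise_sd: float = 0.0,
    seed: int = 0,
    frames_per_window: int = FRAMES_PER_WINDOW,
    fps: float = FPS,
    subject_id: str = "synthetic",
) -> Session:
    """Construct a full four-window session realizing the feature targets.

    At ``noise_sd = 0`` the extraction is the exact inverse: the
    recovered feature vector equals the targets to numerical precision.
    With noise, independent isotropic Gaussian jitter of SD ``noise_sd``
    metres is added to every landmark of every frame.  The corrected-stance
    windows repeat the same target posture (with fresh noise); a corrected
    stance is not modelled separately.
    """
    rng = np.random.default_rng(seed)
    layouts = {"frontal": _frontal_layout(targets), "lateral": _lateral_layout(targets)}
    window_len = frames_per_window / fps
    frames = []
    windows = {}
    t0 = 0.0
    for view in ("frontal", "lateral"):
        base = _embed(layouts[view], view)
        for phase in ("relaxed", "corrected"):
            windows[f"{view}_{phase}"] = (t0, t0 + window_len)
            for i in range(frames_per_window):
                positions = {
                    name: base[name] + rng.normal(0.0, noise_sd, 3)
                    if noise_sd > 0
                    else base[name]
                    for name in LANDMARKS
                }
                frames.append(
                    LandmarkFrame(time=t0 + i / fps, view=view, positions=positions)
                )
            t0 += window_len
    return Session(subject_id=subject_id, frames=frames, windows=windows)


def random_targets(rng: np.random.Generator, **anthropometry) -> FeatureTargets:
    """A random satisfiable target vector, for round-trip testing.

    F4 > F5 is enforced and F7 is capped so the fulcrum stays within the
    anatomical reach bound.
    """
    f1 = rng.uniform(0.0, 20.0)
    f2 = rng.uniform(0.0, 10.0)
    f3 = rng.uniform(0.0, 60.0)
    f4 = rng.uniform(5.0, 45.0)
    f5 = rng.uniform(0.5, 0.9) * f4
    f7_max = min(50.0, 100.0 * MAX_FC_REACH * abs(np.sin(np.radians(f4 - f5))))
    f7 = rng.uniform(0.2, 0.95) * f7_max
    return FeatureTargets(f1=f1, f2=f2, f3=f3, f4=f4, f5=f5, f7=f7, **anthropometry)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class GroupSpec:
    """Group distributions for cohort simulation.

    ``means``/``sds`` map group -> feature -> value; ``sizes`` gives the
    number of subjects per group; ``ipa_sds`` optionally gives the target
    SD of the summary index per group, from which the within-group
    equicorrelation is identified (``None`` or a missing group means
    independent features).  Defaults are the published study groups.
    """

    means: dict = field(default_factory=lambda: {g: dict(v) for g, v in TABLE1_FEATURE_MEANS.items()})
    sds: dict = field(default_factory=lambda: {g: dict(v) for g, v in TABLE1_FEATURE_SDS.items()})
    sizes: dict = field(default_factory=lambda: dict(TABLE1_SIZES))
    ipa_sds: dict | None = field(default_factory=lambda: dict(TABLE1_IPA_SDS))
    seed: int = 0

    def __post_init__(self):
        for group in self.sizes:
            if self.sizes[group] < 2:
                raise ValueError(f"group {group!r}: size must be >= 2")
            if group not in self.means or group not in self.sds:
                raise ValueError(f"group {group!r}: missing means or sds")
            for f in FEATURE_NAMES:
                if self.sds[group][f] <= 0:
                    raise ValueError(f"group {group!r}, {f}: SD must be > 0")

    def with_sizes(self, n: int) -> "GroupSpec":
        return replace(self, sizes={g: n for g in self.sizes})


def _censored_mean(m: float, sigma: float) -> float:
    """Mean of max(0, X) for X ~ N(m, sigma^2)."""
    a = m / sigma
    return m * sps.norm.cdf(a) + sigma * sps.norm.pdf(a)


def _compensated_mean(target: float, sigma: float) -> float:
    """Underlying normal mean whose zero-censored mean equals ``target``."""
    if target <= 0:
        raise ValueError("group feature means must be > 0")
    if sigma == 0.0 or target / sigma > 8.0:  # censoring mass negligible
        return target
    lo = min(0.0, target) - 12.0 * sigma
    return float(optimize.brentq(lambda m: _censored_mean(m, sigma) - target, lo, target))


def _equicorrelation(sds: np.ndarray, weights: np.ndarray, ipa_sd: float) -> float:
    """Common pairwise correlation reproducing a target index SD.

    Var(IPA) = (1 - rho) * sum(w_i^2 s_i^2) + rho * (sum(w_i s_i))^2 for an
    equicorrelated feature vector; solve for rho and clip to [0, 0.999].
    """
    ws = weights * sds
    s2 = float(np.sum(ws**2))
    s1 = float(np.sum(ws)) ** 2
    rho = (ipa_sd**2 - s2) / (s1 - s2)
    return float(np.clip(rho, 0.0, 0.999))


def simulate_cohort(
    spec: GroupSpec | None = None,
    seed: int | None = None,
    weights: IPAWeights = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Draw a cohort feature table from the group distributions.

    Returns a table with subject_id, group, F1..F5, F7 and the summary
    index per subject.  Deterministic given the seed (``seed`` overrides
    ``spec.seed``).
    """
    spec = spec or GroupSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    w = weights.as_array()
    rows = []
    for group in spec.sizes:  # insertion order: deterministic
        n = spec.sizes[group]
        mu = np.array([spec.means[group][f] for f in FEATURE_NAMES])
        sd = np.array([spec.sds[group][f] for f in FEATURE_NAMES])
        ipa_sd = (spec.ipa_sds or {}).get(group)
        rho = _equicorrelation(sd, w, ipa_sd) if ipa_sd else 0.0
        mu_under = np.array([_compensated_mean(m, s) for m, s in zip(mu, sd)])
        z0 = rng.standard_normal((n, 1))
        zi = rng.standard_normal((n, 6))
        x = mu_under + sd * (np.sqrt(rho) * z0 + np.sqrt(1.0 - rho) * zi)
        feats = np.maximum(x, 0.0)
        for i in range(n):
            row = {"subject_id": f"{group}_{i:04d}", "group": group}
            row.update(dict(zip(FEATURE_NAMES, feats[i])))
            row["IPA"] = compute_ipa(feats[i], weights)
            rows.append(row)
    return pd.DataFrame(rows)


def _spec_ipa_moments(spec: GroupSpec, group: str, w: np.ndarray) -> tuple[float, float]:
    mu = np.array([spec.means[group][f] for f in FEATURE_NAMES])
    mean = float(mu @ w)
    ipa_sd = (spec.ipa_sds or {}).get(group)
    if ipa_sd is None:
        sd = np.array([spec.sds[group][f] for f in FEATURE_NAMES])
        ipa_sd = float(np.sqrt(np.sum((w * sd) ** 2)))
    return mean, float(ipa_sd)


def run_validation_study(
    spec: GroupSpec | None = None,
    seed: int = 0,
    weights: IPAWeights = DEFAULT_WEIGHTS,
) -> dict:
    """Synthetic replication of the clinical validation workflow.

    Simulates a cohort, compares every feature and the index between the
    two PD subgroups and between all-PD and controls, runs ROC analyses
    for PD-vs-HC and PwPA-vs-PwtPA, and reports the binormal-theory AUC
    implied by the configured group moments next to each empirical AUC.
    The PD-vs-HC arm uses the pooled all-PD marginal group ("PD"), whose
    published moments the binormal oracle is defined on.
    """
    spec = spec or GroupSpec()
    cohort = simulate_cohort(spec, seed=seed, weights=weights)
    w = weights.as_array()
    variables = list(FEATURE_NAMES) + ["IPA"]

    group_means = cohort.groupby("group")[variables].mean()
    present = set(cohort["group"])
    step_like = {}
    if {"HC", "PwtPA", "PwPA"} <= present:
        for f in FEATURE_NAMES:
            step_like[f] = bool(
                group_means.loc["HC", f]
                < group_means.loc["PwtPA", f]
                < group_means.loc["PwPA", f]
            )

    comparisons: dict[tuple[str, str], dict[str, GroupComparison]] = {}
    for pair in (("PwtPA", "PwPA"), ("HC", "PD")):
        if set(pair) <= present:
            comparisons[pair] = {
                v: compare_groups(cohort, v, pair) for v in variables
            }

    rocs = {}
    for name, pos, neg in (("PD_vs_HC", "PD", "HC"), ("PwPA_vs_PwtPA", "PwPA", "PwtPA")):
        if {pos, neg} <= present:
            sub = cohort[cohort["group"].isin((pos, neg))]
            empirical = roc_youden(sub["IPA"], sub["group"] == pos)
            m1, s1 = _spec_ipa_moments(spec, pos, w)
            m0, s0 = _spec_ipa_moments(spec, neg, w)
            rocs[name] = {
                "empirical": empirical,
                "binormal_auc": binormal_auc(m1, s1, m0, s0),
            }

    return {
        "cohort": cohort,
        "group_means": group_means,
        "step_like_ordering": step_like,
        "comparisons": comparisons,
        "roc": rocs,
        "note": (
            "Features are drawn as equicorrelated censored Gaussians matching the "
            "published group marginals and index SDs; real features are skewed and "
            "more richly correlated, so empirical discriminability of a real cohort "
            "may differ."
        ),
    }
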
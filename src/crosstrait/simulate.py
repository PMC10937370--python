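"""Seeded synthetic-data generators matching the models' assumptions.

Two generators make every module testable without external downloads:

* bivariate effect pairs drawn from a line-model mixture (true effects
  from the class prior covariance, observed estimates with per-variant
  Gaussian estimation noise, optionally correlated across traits), with
  the true class labels and true effects returned as ground truth;
* registry event streams (deliveries plus ICD/registry events) whose
  rule-based phenotype is known by construction, because inclusion and
  exclusion events are planted in unambiguous temporal positions.

All randomness flows through a single seeded numpy Generator per call;
there is no global random state. Simulated dates are synthetic and carry
no calendar semantics beyond ordering.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linemodels import LineModel, prior_covariance
from .pairs import as_pairs_frame
from .phenotyping import PersonStatus

__all__ = [
    "EffectSimConfig",
    "RegistrySimConfig",
    "simulate_effect_pairs",
    "simulate_registry",
]


@dataclass(frozen=True)
class EffectSimConfig:
    """Configuration for the bivariate effect-pair simulator.

    Defaults mirror the gestational-diabetes application: two classes
    with slopes 1.53 (T2D-predominant) and 0.25 (GDM-predominant), scale
    0.2, correlation 0.99, equal weights, uncorrelated estimators, and
    GWAS-scale standard errors.
    """

    n_variants: int = 100
    classes: tuple = (
        LineModel("T", slope=1.53, scale=0.2, cor=0.99, prior_weight=0.5),
        LineModel("G", slope=0.25, scale=0.2, cor=0.99, prior_weight=0.5),
    )
    se_range_x: tuple = (0.01, 0.05)
    se_range_y: tuple = (0.01, 0.05)
    r_est: float = 0.0
    seed: int = 0

    def __post_init__(self):
        w = sum(m.prior_weight for m in self.classes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"class weights must sum to 1 (got {w})")
        for rng in (self.se_range_x, self.se_range_y):
            if not (0 < rng[0] <= rng[1]):
                raise ValueError(f"invalid se range {rng}")
        if not abs(self.r_est) < 1:
            raise ValueError("|r_est| must be < 1")


def simulate_effect_pairs(config: EffectSimConfig
                          ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw effect pairs from a line-model mixture with estimation noise.

    Per variant: a class is drawn by prior weight; the true effect pair
    from ``N(0, Sigma_class)``; the observed pair from a Gaussian centred
    on the truth with covariance built from uniformly drawn standard
    errors and the configured estimator correlation.

    Returns
    -------
    (pairs, labels, true_effects)
        ``pairs`` is a pairs DataFrame (``variant_id, beta_x, se_x,
        beta_y, se_y, r_est``), ``labels`` the true class label per
        variant, ``true_effects`` the n x 2 matrix of noise-free effects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    weights = np.array([m.prior_weight for m in config.classes])
    ks = rng.choice(len(config.classes), size=n, p=weights)

    covs = []
    for m in config.classes:
        cov = prior_covariance(m)
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError(f"class {m.label}: prior covariance not PSD")
        covs.append(cov)

    true = np.empty((n, 2))
    for k, cov in enumerate(covs):
        idx = np.where(ks == k)[0]
        if len(idx):
            true[idx] = rng.multivariate_normal([0.0, 0.0], cov,
                                                size=len(idx),
                                                method="eigh")
    se_x = rng.uniform(*config.se_range_x, size=n)
    se_y = rng.uniform(*config.se_range_y, size=n)
    # correlated estimation noise via a Cholesky-style construction
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    r = config.r_est
    eps_x = se_x * z1
    eps_y = se_y * (r * z1 + np.sqrt(1.0 - r**2) * z2)
    pairs = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "beta_x": true[:, 0] + eps_x,
        "se_x": se_x,
        "beta_y": true[:, 1] + eps_y,
        "se_y": se_y,
        "r_est": r,
    })
    labels = np.array([config.classes[k].label for k in ks])
    return as_pairs_frame(pairs), labels, true


@dataclass(frozen=True)
class RegistrySimConfig:
    """Configuration for the registry event-stream simulator.

    Probabilities are per pregnancy for inclusion events (GDM code inside
    the window, abnormal-glucose registry marker at delivery) and per
    person for pre-existing exclusions (diabetes or pancreatic disease
    planted before the first pregnancy window).
    """

    n_persons: int = 100
    max_pregnancies: int = 3
    p_gdm_code: float = 0.15
    p_abnormal_glucose: float = 0.05
    p_prior_diabetes: float = 0.05
    p_pancreatic: float = 0.02
    p_noise_event: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("p_gdm_code", "p_abnormal_glucose", "p_prior_diabetes",
                     "p_pancreatic", "p_noise_event"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.max_pregnancies < 1:
            raise ValueError("max_pregnancies must be >= 1")


def simulate_registry(config: RegistrySimConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame,
                                 list[PersonStatus]]:
    """Emit deliveries, events and planted person-level truth.

    Every person has 1..max_pregnancies deliveries spaced >= 400 days
    apart (windows never overlap). Exclusion events (T2D or pancreatic
    codes) are planted 300-1500 days before the first window so they are
    strictly previous and outside every window; GDM codes are planted
    inside their pregnancy window; abnormal-glucose registry markers are
    attached to the delivery date. Unrelated noise codes (hypertension
    I10, and an unknown vocabulary) never touch the rule code sets.

    Returns
    -------
    (events, deliveries, truth)
        TSV-ready DataFrames plus the planted
        :class:`~crosstrait.phenotyping.PersonStatus` list.
    """
    rng = np.random.default_rng(config.seed)
    base = dt.date(2000, 1, 1)
    ev_rows, del_rows, truth = [], [], []
    for i in range(config.n_persons):
        pid = f"p{i:05d}"
        n_preg = int(rng.integers(1, config.max_pregnancies + 1))
        first = base + dt.timedelta(days=int(rng.integers(0, 3000)))
        deliveries = [first]
        for _ in range(n_preg - 1):
            deliveries.append(deliveries[-1]
                              + dt.timedelta(days=int(rng.integers(400, 900))))
        for d in deliveries:
            del_rows.append((pid, d.isoformat()))
        first_window_start = deliveries[0] - dt.timedelta(days=280)

        excluded = False
        if rng.random() < config.p_prior_diabetes:
            when = first_window_start - dt.timedelta(
                days=int(rng.integers(300, 1500)))
            ev_rows.append((pid, when.isoformat(), "ICD-10", "E11.9"))
            excluded = True
        if rng.random() < config.p_pancreatic:
            when = first_window_start - dt.timedelta(
                days=int(rng.integers(300, 1500)))
            ev_rows.append((pid, when.isoformat(), "ICD-10", "K86.1"))
            excluded = True

        n_gdm = 0
        for d in deliveries:
            has_incl = False
            if rng.random() < config.p_gdm_code:
                offset = int(rng.integers(0, 200))
                when = d - dt.timedelta(days=offset)
                ev_rows.append((pid, when.isoformat(), "ICD-10", "O24.4"))
                has_incl = True
            if rng.random() < config.p_abnormal_glucose:
                ev_rows.append((pid, d.isoformat(), "REGISTRY", "ABN_GLUC"))
                has_incl = True
            if rng.random() < config.p_noise_event:
                when = d - dt.timedelta(days=int(rng.integers(0, 2000)))
                vocab, code = [("ICD-10", "I10"), ("LOCAL", "XYZ")][
                    int(rng.integers(0, 2))]
                ev_rows.append((pid, when.isoformat(), vocab, code))
            n_gdm += int(has_incl)

        if excluded:
            status, n_gdm_final = "EXCLUDED", 0
        elif n_gdm:
            status, n_gdm_final = "CASE", n_gdm
        else:
            status, n_gdm_final = "CONTROL", 0
        truth.append(PersonStatus(person_id=pid, status=status,
                                  n_pregnancies=n_preg,
                                  n_gdm_pregnancies=n_gdm_final))

    events = pd.DataFrame(ev_rows, columns=["person_id", "date",
                                            "vocabulary", "code"])
    deliveries = pd.DataFrame(del_rows,
                              columns=["person_id", "delivery_date"])
    return events, deliveries, truth
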
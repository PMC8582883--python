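"""Declarative model specification.

A :class:`ModelSpec` states which covariate enters which severity
function, whether its coefficient is fixed or random across crashes, and
— for random coefficients — which covariates shift the coefficient's
mean (the ``Z`` links, slope ``theta``) and which scale its standard
deviation (the ``W`` links, slope ``omega``).  The baseline severity's
function is identically zero, and an alternative-specific constant is
always estimated for each non-baseline severity.

Parameter vector layout (total and stable across runs)::

    constants (non-baseline levels, ascending code)
    fixed-slot coefficients (declaration order)
    random-slot base means   (declaration order)
    random-slot base SDs     (sigma, declaration order)
    mean-heterogeneity links (theta, per slot then per Z covariate)
    variance-heterogeneity links (omega, per slot then per W covariate)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import LABEL_TO_CODE, SEVERITY_CODES, SEVERITY_LABELS, CrashDataset

CONSTANT = "_constant_"


class ConfigError(ValueError):
    """The model configuration is inconsistent with itself or the data."""


def _as_code(severity) -> int:
    if isinstance(severity, str):
        s = severity.strip()
        if s in LABEL_TO_CODE:
            return LABEL_TO_CODE[s]
        try:
            severity = int(s)
        except ValueError:
            raise ConfigError(f"unknown severity {severity!r}") from None
    code = int(severity)
    if code not in SEVERITY_CODES:
        raise ConfigError(f"unknown severity code {code}")
    return code


@dataclass(frozen=True)
class CoefficientSlot:
    """One (covariate, severity) coefficient, fixed or random.

    ``severity`` may be given as a code (2–4) or a label ("severe")."""

    covariate: str
    severity: int
    kind: str = "fixed"  # "fixed" | "random"

    def __post_init__(self):
        object.__setattr__(self, "severity", _as_code(self.severity))
        if self.kind not in ("fixed", "random"):
            raise ConfigError(f"unknown slot kind {self.kind!r}")

    @property
    def name(self) -> str:
        return f"{self.covariate}[{SEVERITY_LABELS[self.severity]}]"


@dataclass(frozen=True)
class RandomSlotSpec:
    """A random coefficient with optional mean/variance heterogeneity.

    The coefficient for crash k realizes as

        beta + theta' Z_k + sigma * exp(omega' W_k) * gamma_k,
        gamma_k ~ N(0, 1)

    so ``mean_covariates`` (Z) shift the mean linearly and
    ``variance_covariates`` (W) scale the SD multiplicatively through the
    exponential.  Only the normal mixing distribution is supported.
    """

    slot: CoefficientSlot
    mean_covariates: tuple[str, ...] = ()
    variance_covariates: tuple[str, ...] = ()
    distribution: str = "normal"

    def __post_init__(self):
        if self.distribution != "normal":
            raise ConfigError(
                f"only the normal mixing distribution is supported, "
                f"got {self.distribution!r}"
            )
        if self.slot.kind != "random":
            object.__setattr__(self, "slot", replace(self.slot, kind="random"))


class ModelSpec:
    """Full model specification for the four-level severity model.

    Parameters
    ----------
    fixed_slots : sequence of CoefficientSlot
        Fixed (non-random) covariate coefficients.
    random_slots : sequence of RandomSlotSpec
        Random coefficients with their heterogeneity links.
    baseline : int
        Severity code whose function is constrained to zero (default 1,
        no injury — the most frequent category).
    """

    def __init__(
        self,
        fixed_slots: Sequence[CoefficientSlot] = (),
        random_slots: Sequence[RandomSlotSpec] = (),
        baseline: int = 1,
    ):
        baseline = _as_code(baseline)
        fixed_slots = tuple(fixed_slots)
        random_slots = tuple(random_slots)
        seen: set[tuple[str, int]] = set()
        for slot in [s for s in fixed_slots] + [r.slot for r in random_slots]:
            if slot.severity == baseline:
                raise ConfigError(
                    f"slot {slot.name} assigned to the baseline severity"
                )
            if slot.covariate == CONSTANT:
                raise ConfigError("constants are implicit; do not declare them")
            key = (slot.covariate, slot.severity)
            if key in seen:
                raise ConfigError(f"duplicate (covariate, severity) pair {key}")
            seen.add(key)
        self.baseline = baseline
        self.fixed_slots = fixed_slots
        self.random_slots = random_slots
        self.nonbase_levels = tuple(c for c in SEVERITY_CODES if c != baseline)
        self._build_layout()

    # ------------------------------------------------------------------
    # parameter layout
    def _build_layout(self) -> None:
        names: list[str] = []
        for lvl in self.nonbase_levels:
            names.append(f"const[{SEVERITY_LABELS[lvl]}]")
        self.sl_const = slice(0, len(names))
        start = len(names)
        for s in self.fixed_slots:
            names.append(s.name)
        self.sl_fixed = slice(start, len(names))
        start = len(names)
        for r in self.random_slots:
            names.append(f"{r.slot.name}:mean")
        self.sl_rmean = slice(start, len(names))
        start = len(names)
        for r in self.random_slots:
            names.append(f"{r.slot.name}:sd")
        self.sl_rsd = slice(start, len(names))
        start = len(names)
        self._theta_index: dict[tuple[int, str], int] = {}
        for q, r in enumerate(self.random_slots):
            for z in r.mean_covariates:
                self._theta_index[(q, z)] = len(names)
                names.append(f"{r.slot.name}:mean~{z}")
        self.sl_theta = slice(start, len(names))
        start = len(names)
        self._omega_index: dict[tuple[int, str], int] = {}
        for q, r in enumerate(self.random_slots):
            for w in r.variance_covariates:
                self._omega_index[(q, w)] = len(names)
                names.append(f"{r.slot.name}:sd~{w}")
        self.sl_omega = slice(start, len(names))
        self._param_names = tuple(names)

    @property
    def param_names(self) -> tuple[str, ...]:
        return self._param_names

    @property
    def n_params(self) -> int:
        return len(self._param_names)

    @property
    def n_random(self) -> int:
        return len(self.random_slots)

    def theta_index(self, q: int, z: str) -> int:
        return self._theta_index[(q, z)]

    def omega_index(self, q: int, w: str) -> int:
        return self._omega_index[(q, w)]

    def covariates_used(self) -> list[str]:
        used: list[str] = []
        for s in self.fixed_slots:
            used.append(s.covariate)
        for r in self.random_slots:
            used.append(r.slot.covariate)
            used.extend(r.mean_covariates)
            used.extend(r.variance_covariates)
        out: list[str] = []
        for u in used:
            if u not in out:
                out.append(u)
        return out

    def validate_against(self, dataset: CrashDataset) -> None:
        missing = [c for c in self.covariates_used() if c not in dataset.covariate_names]
        if missing:
            raise ConfigError(f"spec references unknown covariate(s): {missing}")
        if not np.any(dataset.outcome == self.baseline):
            raise ConfigError(
                "no crash in the baseline category; constants are not estimable"
            )

    # ------------------------------------------------------------------
    # the three-model ladder
    def without_links(self, drop_means: bool, drop_variances: bool) -> "ModelSpec":
        new_random = tuple(
            RandomSlotSpec(
                slot=r.slot,
                mean_covariates=() if drop_means else r.mean_covariates,
                variance_covariates=() if drop_variances else r.variance_covariates,
                distribution=r.distribution,
            )
            for r in self.random_slots
        )
        return ModelSpec(self.fixed_slots, new_random, self.baseline)

    def nested_ladder(self) -> tuple["ModelSpec", "ModelSpec", "ModelSpec"]:
        """The three nested specifications estimated in sequence:

        1. random parameters, no heterogeneity (all Z and W links removed),
        2. heterogeneity in means only (W links removed),
        3. heterogeneity in means and variances (this spec, unchanged).
        """
        return (
            self.without_links(drop_means=True, drop_variances=True),
            self.without_links(drop_means=False, drop_variances=True),
            self,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ModelSpec)
            and self.baseline == other.baseline
            and self.fixed_slots == other.fixed_slots
            and self.random_slots == other.random_slots
        )

    def __repr__(self) -> str:
        return (
            f"ModelSpec(baseline={self.baseline}, "
            f"{len(self.fixed_slots)} fixed, {len(self.random_slots)} random, "
            f"{self.n_params} parameters)"
        )


def build_spec(config: Mapping, dataset: CrashDataset | None = None) -> ModelSpec:
    """Build a :class:`ModelSpec` from a plain configuration mapping.

    Schema::

        baseline: 1                     # optional, code or label
        fixed:                          # per-severity covariate lists
          minor:  [covariate, ...]
          severe: [covariate, ...]
          fatal:  [covariate, ...]
        random:
          - covariate: some_indicator
            severity: severe
            mean_covariates: [a, b]     # optional (Z)
            variance_covariates: [c]    # optional (W)

    When ``dataset`` is given, every referenced covariate must exist in it.
    """
    baseline = _as_code(config.get("baseline", 1))
    fixed: list[CoefficientSlot] = []
    for sev_key, covs in (config.get("fixed") or {}).items():
        code = _as_code(sev_key)
        for cov in covs or []:
            fixed.append(CoefficientSlot(covariate=str(cov), severity=code))
    random: list[RandomSlotSpec] = []
    for block in config.get("random") or []:
        slot = CoefficientSlot(
            covariate=str(block["covariate"]),
            severity=_as_code(block.get("severity", 3)),
            kind="random",
        )
        random.append(
            RandomSlotSpec(
                slot=slot,
                mean_covariates=tuple(block.get("mean_covariates") or ()),
                variance_covariates=tuple(block.get("variance_covariates") or ()),
                distribution=str(block.get("distribution", "normal")),
            )
        )
    spec = ModelSpec(fixed, random, baseline)
    if dataset is not None:
        spec.validate_against(dataset)
    return spec


@dataclass
class CoefficientSet:
    """All estimable parameters of a spec, as a named flat vector.

    The base SD ``sigma`` is stored unconstrained (its sign is not
    identified under normal mixing); report ``abs(sigma)``.
    """

    spec: ModelSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.spec.n_params,):
            raise ValueError(
                f"expected {self.spec.n_params} parameter values, "
                f"got shape {self.values.shape}"
            )

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "CoefficientSet":
        return cls(spec, np.zeros(spec.n_params))

    @classmethod
    def from_values(
        cls,
        spec: ModelSpec,
        constants: Mapping[int, float] | None = None,
        betas: Mapping[tuple[str, int], float] | None = None,
        means: Mapping[tuple[str, int], float] | None = None,
        sds: Mapping[tuple[str, int], float] | None = None,
        thetas: Mapping[tuple[str, int, str], float] | None = None,
        omegas: Mapping[tuple[str, int, str], float] | None = None,
    ) -> "CoefficientSet":
        """Assemble a parameter vector from named pieces.

        Keys: constants by severity code; fixed betas and random means/sds
        by (covariate, severity); theta/omega links by
        (covariate, severity, link covariate).  Unnamed entries are zero.
        """
        v = np.zeros(spec.n_params)
        for code, val in (constants or {}).items():
            v[spec.nonbase_levels.index(_as_code(code))] = val
        fixed_keys = [(s.covariate, s.severity) for s in spec.fixed_slots]
        for key, val in (betas or {}).items():
            v[spec.sl_fixed.start + fixed_keys.index((key[0], _as_code(key[1])))] = val
        rand_keys = [(r.slot.covariate, r.slot.severity) for r in spec.random_slots]
        for key, val in (means or {}).items():
            v[spec.sl_rmean.start + rand_keys.index((key[0], _as_code(key[1])))] = val
        for key, val in (sds or {}).items():
            v[spec.sl_rsd.start + rand_keys.index((key[0], _as_code(key[1])))] = val
        for (cov, sev, z), val in (thetas or {}).items():
            q = rand_keys.index((cov, _as_code(sev)))
            v[spec.theta_index(q, z)] = val
        for (cov, sev, w), val in (omegas or {}).items():
            q = rand_keys.index((cov, _as_code(sev)))
            v[spec.omega_index(q, w)] = val
        return cls(spec, v)

    # named accessors -------------------------------------------------
    def constant(self, severity) -> float:
        return float(self.values[self.spec.nonbase_levels.index(_as_code(severity))])

    def beta(self, covariate: str, severity) -> float:
        keys = [(s.covariate, s.severity) for s in self.spec.fixed_slots]
        return float(
            self.values[self.spec.sl_fixed.start + keys.index((covariate, _as_code(severity)))]
        )

    def _rq(self, covariate: str, severity) -> int:
        keys = [(r.slot.covariate, r.slot.severity) for r in self.spec.random_slots]
        return keys.index((covariate, _as_code(severity)))

    def random_mean(self, covariate: str, severity) -> float:
        return float(self.values[self.spec.sl_rmean.start + self._rq(covariate, severity)])

    def random_sd(self, covariate: str, severity) -> float:
        return abs(float(self.values[self.spec.sl_rsd.start + self._rq(covariate, severity)]))

    def theta(self, covariate: str, severity, z: str) -> float:
        return float(self.values[self.spec.theta_index(self._rq(covariate, severity), z)])

    def omega(self, covariate: str, severity, w: str) -> float:
        return float(self.values[self.spec.omega_index(self._rq(covariate, severity), w)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.spec.param_names, self.values.tolist()))
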
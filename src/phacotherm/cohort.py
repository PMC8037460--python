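"""Synthetic patient cohort emulating the clinical study's endpoints.

The raw per-eye data behind the study are not public; this module draws a
per-patient table whose group sizes, endpoint means and SDs match the
printed summary statistics (BSS irrigation group n=47, Healon viscoelastic
group n=45).  Longitudinal endpoints (ECD, IOP, BCVA) are drawn from a
correlated multivariate normal per patient — compound-symmetric
within-patient correlation ``rho_w`` across timepoints — so both the
cross-sectional SDs and realistic paired-change SDs are reproduced.  The
printed one-month ECD loss SDs (226 / 207 cells/mm^2 on cross-sectional
SDs near 450) imply rho_w ~ 0.88; see ``rho_for_loss_sd``.

IOP means after surgery are printed only as a figure; the 6-h values used
here are mildly elevated with an SD wide enough to produce occasional
transient peaks above 20 mmHg, as described clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ECD_TIMEPOINTS = ("pre", "1d", "1w", "1m")
IOP_TIMEPOINTS = ("pre", "6h", "1d", "1w", "1m")


class CohortSpecError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """Endpoint summary statistics of one treatment arm."""

    name: str
    n: int
    n_female: int
    age: tuple[float, float]                  # mean, SD [years]
    ecd: tuple[float, ...]                    # cells/mm^2, 4 timepoints
    ecd_sd: tuple[float, ...]
    iop: tuple[float, ...]                    # mmHg, 5 timepoints
    iop_sd: tuple[float, ...]
    bcva: tuple[float, ...]                   # decimal acuity, 4 timepoints
    bcva_sd: tuple[float, ...]
    ave: tuple[float, float]                  # mean cell area [um^2]
    cv: tuple[float, float]                   # area variation coefficient [%]
    hex_pct: tuple[float, float]              # hexagonal cells [%]
    phaco_time: tuple[float, float]           # [s]
    ept: tuple[float, float]                  # effective phaco time [s]
    locs3: tuple[float, float]                # cataract grade

    def validate(self):
        if self.n < 2:
            raise CohortSpecError(f"group {self.name}: n must be >= 2")
        if not 0 <= self.n_female <= self.n:
            raise CohortSpecError(f"group {self.name}: bad n_female")
        for nm in ("ecd_sd", "iop_sd", "bcva_sd"):
            if any(s < 0 for s in getattr(self, nm)):
                raise CohortSpecError(f"group {self.name}: negative {nm}")
        for nm in ("age", "ave", "cv", "hex_pct", "phaco_time", "ept",
                   "locs3"):
            if getattr(self, nm)[1] < 0:
                raise CohortSpecError(f"group {self.name}: negative {nm} SD")


def _default_bss() -> GroupSpec:
    return GroupSpec(
        name="BSS", n=47, n_female=32, age=(71.2, 9.7),
        ecd=(2334, 2250, 2211, 2228), ecd_sd=(436, 472, 485, 471),
        iop=(15.2, 17.0, 15.0, 14.5, 14.3),
        iop_sd=(3.8, 4.2, 3.5, 3.2, 3.0),
        bcva=(0.30, 0.72, 0.74, 0.88), bcva_sd=(0.14, 0.18, 0.18, 0.18),
        ave=(457.7, 252.0), cv=(34.7, 5.9), hex_pct=(60.4, 8.0),
        phaco_time=(1.62, 0.60), ept=(1.31, 0.49), locs3=(2.40, 0.81))


def _default_healon() -> GroupSpec:
    return GroupSpec(
        name="Healon", n=45, n_female=30, age=(71.2, 10.6),
        ecd=(2307, 2243, 2195, 2185), ecd_sd=(427, 435, 452, 389),
        iop=(13.9, 15.8, 14.2, 14.0, 13.8),
        iop_sd=(2.7, 3.9, 3.0, 2.8, 2.7),
        bcva=(0.39, 0.68, 0.88, 0.92), bcva_sd=(0.14, 0.19, 0.17, 0.22),
        ave=(452.3, 126.0), cv=(34.9, 5.1), hex_pct=(58.8, 8.0),
        phaco_time=(1.75, 0.89), ept=(1.40, 0.71), locs3=(2.16, 0.95))


@dataclass(frozen=True)
class CohortSpec:
    """Study design: two arms plus the longitudinal correlation model."""

    bss: GroupSpec = field(default_factory=_default_bss)
    healon: GroupSpec = field(default_factory=_default_healon)
    rho_w: float = 0.85            # within-patient correlation
    age_ecl_slope: float = 2.5     # extra postoperative ECD loss per year
                                   # of age above the group mean [cells/mm^2]

    def __post_init__(self):
        if not 0 <= self.rho_w < 1:
            raise CohortSpecError("rho_w must lie in [0, 1)")
        self.bss.validate()
        self.healon.validate()

    @property
    def groups(self) -> tuple[GroupSpec, GroupSpec]:
        return (self.bss, self.healon)


def rho_for_loss_sd(sd_pre: float, sd_post: float, loss_sd: float) -> float:
    """Within-patient correlation for which Var(pre - post) hits loss_sd.

    rho = (sd_pre^2 + sd_post^2 - loss_sd^2) / (2 sd_pre sd_post); raises
    if the implied correlation is infeasible.
    """
    rho = (sd_pre**2 + sd_post**2 - loss_sd**2) / (2 * sd_pre * sd_post)
    if not -1 < rho < 1:
        raise CohortSpecError(
            f"loss SD {loss_sd} infeasible for marginal SDs "
            f"{sd_pre}, {sd_post}")
    return float(rho)


def _correlated(rng, mean, sd, rho, n):
    """(n, k) draws, compound-symmetric correlation rho across columns."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    k = len(mean)
    R = np.full((k, k), rho) + np.eye(k) * (1 - rho)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, k))
    return mean + (z @ L.T) * sd


def generate_cohort(spec: CohortSpec | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Draw one synthetic cohort table (one row per patient).

    Deterministic for a given seed.  ECD and IOP are truncated to
    positive values; BCVA to (0.01, 1.6); operative times to >= 0.05 s.
    The optional age effect shifts every postoperative ECD down by
    ``age_ecl_slope`` cells/mm^2 per year of age above the group mean, so
    older patients lose more cells (set the slope to 0 to disable).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    frames = []
    for g in spec.groups:
        age = np.clip(rng.normal(g.age[0], g.age[1], g.n), 18, 105)
        ecd = _correlated(rng, g.ecd, g.ecd_sd, spec.rho_w, g.n)
        ecd[:, 1:] -= spec.age_ecl_slope * (age[:, None] - g.age[0])
        ecd = np.maximum(ecd, 1.0)
        iop = np.maximum(_correlated(rng, g.iop, g.iop_sd, spec.rho_w, g.n),
                         1.0)
        bcva = np.clip(_correlated(rng, g.bcva, g.bcva_sd, spec.rho_w, g.n),
                       0.01, 1.6)
        sex = np.array(["F"] * g.n_female + ["M"] * (g.n - g.n_female))
        rng.shuffle(sex)
        df = pd.DataFrame({
            "group": g.name,
            "patient_id": [f"{g.name}-{i + 1:03d}" for i in range(g.n)],
            "age": age, "sex": sex,
        })
        for j, tp in enumerate(ECD_TIMEPOINTS):
            df[f"ecd_{tp}"] = ecd[:, j]
        for j, tp in enumerate(IOP_TIMEPOINTS):
            df[f"iop_{tp}"] = iop[:, j]
        for j, tp in enumerate(ECD_TIMEPOINTS):
            df[f"bcva_{tp}"] = bcva[:, j]
        df["ave_pre"] = np.maximum(
            rng.normal(g.ave[0], g.ave[1], g.n), 50.0)
        df["cv_pre"] = np.maximum(rng.normal(g.cv[0], g.cv[1], g.n), 1.0)
        df["hex_pre"] = np.clip(
            rng.normal(g.hex_pct[0], g.hex_pct[1], g.n), 0.0, 100.0)
        df["phaco_time_s"] = np.maximum(
            rng.normal(g.phaco_time[0], g.phaco_time[1], g.n), 0.05)
        df["ept_s"] = np.maximum(rng.normal(g.ept[0], g.ept[1], g.n), 0.05)
        df["locs3"] = np.clip(rng.normal(g.locs3[0], g.locs3[1], g.n),
                              1.0, 6.9)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
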
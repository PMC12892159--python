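"""Group comparison of sector-occupancy profiles, and experiment simulation.

The unit of replication is the cochlea (one profile per sample): per
sector, per-sample frequencies are compared between genotypes with a
two-sided two-sample t-test (Student by default, Welch by flag). Raw p
drives the significance stars — matching how per-sector asterisks are
conventionally placed on the radar plots — and Benjamini–Hochberg adjusted
p across the 16 sectors is always reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import synthetic
from .exceptions import InsufficientDataError
from .mosaic import Mosaic
from .star import SectorProfile, StarConfig, aggregate_group, compute_profile


@dataclass(frozen=True)
class TestOptions:
    welch: bool = False
    alpha_star: float = 0.05      # "*" threshold (single-star level)
    alpha_double_star: float = 0.01
    label_on: str = "p_raw"       # column the stars are applied to


@dataclass(frozen=True)
class SectorTestResult:
    sector: int
    mean_freq_group1: float
    mean_freq_group2: float
    t_stat: float
    p_raw: float
    p_bh: float
    significance_label: str
    degenerate: bool


def _freq_matrix(profiles: list[SectorProfile]) -> np.ndarray:
    return np.stack([p.frequencies for p in profiles])


def sector_ttest(
    group1: list[SectorProfile],
    group2: list[SectorProfile],
    options: TestOptions = TestOptions(),
) -> pd.DataFrame:
    """Per-sector two-sample t-tests between two groups of profiles.

    Returns one row per sector with means, t, raw p, BH-adjusted p, the
    significance label, and a degenerate flag for sectors where both groups
    have zero variance (t undefined; reported as not significant).
    """
    if len(group1) < 2 or len(group2) < 2:
        raise InsufficientDataError(
            f"need >= 2 samples per group, got {len(group1)} and {len(group2)}"
        )
    n_sectors = {p.n_sectors for p in group1 + group2}
    if len(n_sectors) != 1:
        raise InsufficientDataError(f"profiles disagree on n_sectors: {sorted(n_sectors)}")
    f1, f2 = _freq_matrix(group1), _freq_matrix(group2)

    rows = []
    for s in range(f1.shape[1]):
        a, b = f1[:, s], f2[:, s]
        degenerate = bool(np.var(a) == 0.0 and np.var(b) == 0.0)
        if degenerate:
            t, p = np.nan, 1.0
        else:
            with warnings.catch_warnings():
                # scipy warns about precision loss when groups are nearly
                # identical; harmless here (t ~ 0, p ~ 1)
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, equal_var=not options.welch)
        rows.append([s + 1, a.mean(), b.mean(), float(t), float(p), degenerate])
    df = pd.DataFrame(
        rows, columns=["sector", "mean_freq_group1", "mean_freq_group2",
                       "t_stat", "p_raw", "degenerate"]
    )
    df["p_bh"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    p_for_label = df[options.label_on]
    df["label"] = np.where(
        df["degenerate"], "",
        np.where(p_for_label < options.alpha_double_star, "**",
                 np.where(p_for_label < options.alpha_star, "*", "")),
    )
    return df[["sector", "mean_freq_group1", "mean_freq_group2",
               "t_stat", "p_raw", "p_bh", "label", "degenerate"]]


@dataclass(frozen=True)
class DisorderSummary:
    sample_id: str
    entropy: float          # bits; log2(16) = 4 at the uniform profile
    occupied_sectors: int


def disorder_summary(profile: SectorProfile) -> DisorderSummary:
    """Shannon entropy (base 2, 0·log0 := 0) and occupied-sector count."""
    if profile.n_focal == 0:
        raise InsufficientDataError(f"profile {profile.sample_id} has no focal cells")
    p = profile.frequencies
    nz = p[p > 0]
    return DisorderSummary(
        sample_id=profile.sample_id,
        entropy=float(-(nz * np.log2(nz)).sum()),
        occupied_sectors=int((p > 0).sum()),
    )


def disorder_frame(profiles: list[SectorProfile]) -> pd.DataFrame:
    rows = [disorder_summary(p) for p in profiles]
    return pd.DataFrame(
        {"sample_id": [r.sample_id for r in rows],
         "genotype": [p.genotype for p in profiles],
         "region": [p.region for p in profiles],
         "entropy_bits": [r.entropy for r in rows],
         "occupied_sectors": [r.occupied_sectors for r in rows]}
    )


@dataclass
class ExperimentReport:
    """Everything the control-vs-mutant patterning comparison produces."""

    control_profiles: list[SectorProfile]
    mutant_profiles: list[SectorProfile]
    radar: pd.DataFrame           # group, sector, mean_frequency
    sector_tests: pd.DataFrame
    disorder: pd.DataFrame
    star_config: StarConfig = field(default_factory=StarConfig)


def run_experiment_comparison(
    control: list[Mosaic],
    mutant: list[Mosaic],
    star_config: StarConfig = StarConfig(),
    options: TestOptions = TestOptions(),
) -> ExperimentReport:
    """Per-sample profiles → group radar means → per-sector tests → disorder.

    Stage errors are re-raised with the stage and sample id prepended.
    """
    def _profiles(mosaics: list[Mosaic], label: str) -> list[SectorProfile]:
        out = []
        for m in mosaics:
            try:
                out.append(compute_profile(m, star_config))
            except Exception as exc:
                raise type(exc)(f"[profile:{label}:{m.sample_id}] {exc}") from exc
        return out

    cp = _profiles(control, "control")
    mp = _profiles(mutant, "mutant")
    radar_rows = []
    for group, profs in (("group1", cp), ("group2", mp)):
        mean = aggregate_group(profs)
        name = profs[0].genotype
        for s, f in enumerate(mean, start=1):
            radar_rows.append({"group": name or group, "sector": s, "mean_frequency": f})
    radar = pd.DataFrame(radar_rows)
    tests = sector_ttest(cp, mp, options)
    disorder = disorder_frame(cp + mp)
    return ExperimentReport(cp, mp, radar, tests, disorder, star_config)


def simulate_cohort(
    config: synthetic.GeneratorConfig, n_samples: int, seed: int
) -> list[Mosaic]:
    """Generate ``n_samples`` mosaics with per-sample seeds derived from one
    master seed (kept below 2^31 for portability)."""
    rng = np.random.default_rng(seed)
    mosaics = []
    for i in range(n_samples):
        sub = int(rng.integers(2**31))
        cfg = replace(config, seed=sub)
        m = synthetic.generate_lattice(cfg)
        m.sample_id = f"{cfg.genotype_label}_{cfg.region_label}_{i + 1}"
        mosaics.append(m)
    return mosaics


def simulate_experiment(
    control_config: synthetic.GeneratorConfig,
    mutant_config: synthetic.GeneratorConfig,
    n_samples: int,
    star_config: StarConfig,
    seed: int,
    options: TestOptions = TestOptions(),
) -> ExperimentReport:
    """One synthetic control-vs-mutant experiment, end to end."""
    rng = np.random.default_rng(seed)
    s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
    control = simulate_cohort(control_config, n_samples, s1)
    mutant = simulate_cohort(mutant_config, n_samples, s2)
    return run_experiment_comparison(control, mutant, star_config, options)
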
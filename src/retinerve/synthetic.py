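"""Synthetic paired RNFL/visual-field data with known ground truth.

Real registries pairing SDOCT scans with 24-2 fields are private, so this
module generates statistically similar data with a *known* structure-function
mapping, enabling end-to-end pipeline tests and parameter-recovery studies.
The generator reproduces four qualitative features of clinical data:

* a long-tailed severity distribution -- most eyes near 0 dB MD, a heavy
  left tail reaching below -26 dB;
* arcuate, sector-wise structure-function coupling: each chart location
  reads the mean thickness loss inside its own angular window (bundle) on
  the scan circle, damage arrives in contiguous arcuate wedges of bundles
  (plus a diffuse component that grows with severity), and a location's TD
  responds only to its own window;
* the SDOCT floor effect: thickness never drops below a residual-tissue
  floor, so measured structure saturates while function keeps worsening;
* severity-dependent perimetric noise: TD noise SD grows linearly from
  1 dB at TD 0 to 4 dB at TD -30 (configurable), reflecting the high
  test-retest variability of damaged fields.

The healthy profile is the classic double-hump TSNIT curve (superior and
inferior peaks, temporal and nasal troughs).  Damage is piecewise-constant
per bundle window, so with the linear link and the floor disabled the true
TD is an exactly linear function of the profile -- the sanity ceiling used
by the parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .records import Dataset, RNFL_COLUMNS, TD_COLUMNS
from .vf_geometry import VFGrid, build_grid, uniform_md_mask

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "healthy_template",
    "bundle_windows",
    "sample_severity",
    "make_profile",
    "td_from_truth",
    "generate_dataset",
]

N_SAMPLES = 768
TD_CLIP = (-38.0, 6.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the simulator.

    Defaults give 2,000 QC-clean records (500 patients x 2 eyes x 2 tests)
    whose severity mixture (70 % near-healthy bulk, 30 % exponential tail)
    qualitatively matches the long-tailed clinical MD histogram, a healthy
    TSNIT template with mean ~89 um calibrated so the early/no-disease group
    averages in the mid-80s um, a 45 um measurement floor, and the
    heteroscedastic TD noise schedule described above.
    """

    n_patients: int = 500
    eyes_per_patient: int = 2
    tests_per_eye: int = 2
    # severity mixture
    healthy_fraction: float = 0.70
    bulk_mean_db: float = -1.5
    bulk_sd_db: float = 2.0
    tail_onset_db: float = -6.0
    tail_scale_db: float = 8.0
    severity_min_db: float = -35.0
    # structure
    template_base_um: float = 58.0
    template_amp_um: float = 58.0
    template_kappa: float = 2.5
    floor_thickness_um: float = 45.0
    rnfl_noise_sd_um: float = 2.0
    # structure-function link
    link: str = "linear"            # "linear" or "loglinear"
    slope_db_per_um: float = 1.0
    # TD noise schedule: SD interpolates linearly noise_sd0 -> noise_sd30
    td_noise_sd0_db: float = 1.0
    td_noise_sd30_db: float = 4.0
    # wedge damage
    max_wedges: int = 3
    wedge_width_windows: Tuple[int, int] = (3, 10)
    md_mask: Optional[Tuple[float, ...]] = None
    seed: int = 0
    target_early_mean_um: float = 87.5

    def __post_init__(self):
        if not self.floor_thickness_um > 0:
            raise ValueError("floor_thickness_um must be > 0")
        for name in ("rnfl_noise_sd_um", "td_noise_sd0_db", "td_noise_sd30_db"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.healthy_fraction <= 1.0:
            raise ValueError("healthy_fraction must be in [0, 1]")
        if self.link not in ("linear", "loglinear"):
            raise ValueError(f"unknown link {self.link!r}")
        for name in ("n_patients", "eyes_per_patient", "tests_per_eye"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def mask(self) -> np.ndarray:
        if self.md_mask is None:
            return uniform_md_mask()
        return np.asarray(self.md_mask, float)


@dataclass
class GroundTruth:
    """Latent state behind one generated record (right-eye convention)."""

    severity_db: float
    true_td: np.ndarray            # (52,) noise-free TD, canonical order
    clean_thickness: np.ndarray    # (768,) pre-noise profile
    damage_per_window: np.ndarray  # (52,) thickness loss per bundle, um


def healthy_template(config: GeneratorConfig) -> np.ndarray:
    """Noise-free healthy TSNIT profile: double-hump von-Mises bumps at the
    superior (90 deg) and inferior (270 deg) poles over a constant base."""
    theta = 2.0 * np.pi * np.arange(N_SAMPLES) / N_SAMPLES
    k = config.template_kappa
    bump = lambda mu: np.exp(k * (np.cos(theta - mu) - 1.0))
    return config.template_base_um + config.template_amp_um * (
        bump(np.pi / 2) + bump(3 * np.pi / 2)
    )


def bundle_windows(grid: Optional[VFGrid] = None) -> np.ndarray:
    """(52, 2) start/stop sample indices of each location's angular window.

    The two hemiretina halves (superior: samples 0..383 serving the inferior
    chart; inferior: 384..767 serving the superior chart) are each tiled by
    26 disjoint windows assigned in canonical (pass, slot) order, i.e. the
    window nearest the temporal pole belongs to the location nearest the
    blind spot and windows march nasally as the passes move outward.  A
    stylized stand-in for the anatomical bundle map, sufficient for the
    locality structure the models exploit.
    """
    grid = grid if grid is not None else build_grid()
    edges = np.round(np.linspace(0, 384, 27)).astype(int)
    win = np.empty((52, 2), dtype=int)
    # canonical order within a hemifield block *is* (pass, slot) order
    for j, loc in enumerate(grid):
        rank = j % 26                      # position within the hemifield block
        half = 0 if loc.hemifield == "inferior_chart" else 1
        win[j] = (edges[rank] + 384 * half, edges[rank + 1] + 384 * half)
    return win


def sample_severity(config: GeneratorConfig, rng: np.random.Generator,
                    size: int = 1) -> np.ndarray:
    """Draw latent MD-scale severities (dB) from the two-component mixture."""
    from scipy import stats

    healthy = rng.random(size) < config.healthy_fraction
    # bulk: normal near 0 dB truncated above at +2 dB
    upper = (2.0 - config.bulk_mean_db) / config.bulk_sd_db
    bulk = stats.truncnorm.rvs(-np.inf, upper, loc=config.bulk_mean_db,
                               scale=config.bulk_sd_db, size=size, random_state=rng)
    tail = config.tail_onset_db - rng.exponential(config.tail_scale_db, size=size)
    sev = np.where(healthy, bulk, tail)
    return np.clip(sev, config.severity_min_db, 2.0)


def _damage_pattern(severity: float, config: GeneratorConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-window relative damage pattern (52,), mean-normalized to 1.

    Wedges are contiguous runs of bundle windows within one hemiretina half;
    a diffuse component grows with severity (advanced disease damages the
    whole circumference), which also keeps the target reachable under the
    measurement floor.
    """
    if severity >= 0:
        return np.zeros(52)
    wedge = np.zeros(52)
    n_wedges = int(rng.integers(1, config.max_wedges + 1))
    lo, hi = config.wedge_width_windows
    for _ in range(n_wedges):
        half = int(rng.integers(0, 2))
        width = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, 26 - width + 1))
        wedge[half * 26 + start: half * 26 + start + width] = 1.0
    diffuse = min(1.0, abs(severity) / 30.0)
    p = (1.0 - diffuse) * wedge + diffuse
    m = p.mean()
    return p / m if m > 0 else p


def _apply_damage(severity: float, pattern: np.ndarray,
                  config: GeneratorConfig,
                  windows: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Clean (pre-noise) profile and realized per-window loss for a record.

    The requested per-window loss is |severity|/slope * pattern; the profile
    is clamped at the measurement floor, so the realized loss (and hence the
    true TD) saturates for extreme severities -- the floor effect.
    """
    template = healthy_template(config)
    clean = template.copy()
    loss_req = (abs(min(severity, 0.0)) / config.slope_db_per_um) * pattern
    for j, (a, b) in enumerate(windows):
        seg = template[a:b] - loss_req[j]
        clean[a:b] = np.maximum(seg, config.floor_thickness_um)
    realized = np.array([
        float(np.mean(template[a:b] - clean[a:b])) for a, b in windows
    ])
    return clean, realized


def _link_td(realized_loss: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Map per-window realized thickness loss (um) to true TD (dB)."""
    if config.link == "linear":
        td = -config.slope_db_per_um * realized_loss
    else:  # loglinear: dB loss proportional to log-relative remaining tissue
        template_mean = healthy_template(config).mean()
        frac = np.clip(1.0 - realized_loss / template_mean, 1e-3, None)
        td = 10.0 * np.log10(frac) * (config.slope_db_per_um * template_mean / 4.343)
    return np.clip(td, TD_CLIP[0], TD_CLIP[1])


def make_profile(severity: float, config: GeneratorConfig,
                 rng: np.random.Generator,
                 windows: Optional[np.ndarray] = None,
                 pattern: Optional[np.ndarray] = None,
                 ) -> Tuple[np.ndarray, GroundTruth]:
    """Generate one measured profile plus its ground truth.

    Returns the noisy thickness vector (clipped at 0) and the GroundTruth
    holding the clean profile, per-window realized loss and true TD.
    """
    windows = windows if windows is not None else bundle_windows()
    pattern = pattern if pattern is not None else _damage_pattern(severity, config, rng)
    clean, realized = _apply_damage(severity, pattern, config, windows)
    true_td = _link_td(realized, config)
    noisy = clean + rng.normal(0.0, config.rnfl_noise_sd_um, size=N_SAMPLES) \
        if config.rnfl_noise_sd_um > 0 else clean.copy()
    noisy = np.clip(noisy, 0.0, None)
    gt = GroundTruth(severity_db=float(severity), true_td=true_td,
                     clean_thickness=clean, damage_per_window=realized)
    return noisy, gt


def td_noise_sd(true_td: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Heteroscedastic TD noise SD: linear in |TD| from sd0 at 0 to sd30 at -30."""
    frac = np.clip(np.abs(np.minimum(true_td, 0.0)) / 30.0, 0.0, 1.0)
    return config.td_noise_sd0_db + (config.td_noise_sd30_db - config.td_noise_sd0_db) * frac


def td_from_truth(gt: GroundTruth, config: GeneratorConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Observed (noisy) TD for a record, clipped to the instrument range."""
    sd = td_noise_sd(gt.true_td, config)
    td = gt.true_td + (rng.normal(0.0, 1.0, size=52) * sd
                       if np.any(sd > 0) else 0.0)
    return np.clip(td, TD_CLIP[0], TD_CLIP[1])


def generate_dataset(config: GeneratorConfig,
                     grid: Optional[VFGrid] = None,
                     ) -> Tuple[Dataset, pd.DataFrame]:
    """Generate a QC-clean paired dataset plus its ground-truth sidecar.

    One latent severity is drawn per eye; repeat tests of the same eye share
    the eye's damage pattern and differ only in measurement noise.  Both
    eyes are emitted in the eye-local (temporal-positive) convention shared
    by the whole package.  Deterministic under ``config.seed``.
    """
    grid = grid if grid is not None else build_grid()
    rng = np.random.default_rng(config.seed)
    windows = bundle_windows(grid)
    mask = config.mask()
    base_date = date(2020, 1, 1)

    rows: List[dict] = []
    truth_rows: List[dict] = []
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        age = float(np.clip(rng.normal(56.0, 18.0), 18.0, 95.0))
        for e in range(config.eyes_per_patient):
            eye = "OD" if e == 0 else "OS"
            severity = float(sample_severity(config, rng, size=1)[0])
            pattern = _damage_pattern(severity, config, rng)
            for t in range(config.tests_per_eye):
                thick, gt = make_profile(severity, config, rng,
                                         windows=windows, pattern=pattern)
                td_obs = td_from_truth(gt, config, rng)
                md = float(gt.true_td @ mask)
                sap_offset = int(rng.integers(0, 365))
                gap = int(rng.integers(-180, 181))
                sap_date = base_date + timedelta(days=sap_offset)
                oct_date = sap_date + timedelta(days=gap)
                row = {
                    "patient_id": pid, "eye": eye, "age": age,
                    "sap_date": sap_date.isoformat(), "oct_date": oct_date.isoformat(),
                    "fixation_loss_pct": float(rng.uniform(0, 33)),
                    "false_positive_pct": float(rng.uniform(0, 15)),
                    "quality_score": float(rng.uniform(15, 40)),
                    "md": md, "split": "",
                }
                row.update(dict(zip(TD_COLUMNS, td_obs)))
                row.update(dict(zip(RNFL_COLUMNS, thick)))
                rows.append(row)
                tr = {"patient_id": pid, "eye": eye, "severity_db": severity}
                tr.update({f"td_true_{j}": v for j, v in enumerate(gt.true_td)})
                truth_rows.append(tr)
    dataset = Dataset(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows)
    return dataset, truth
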
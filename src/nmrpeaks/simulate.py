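"""Synthetic 1D NMR spectra with planted ground truth.

Each spectrum is a mixture of two metabolite templates (Lorentzian lines),
weighted (1 - m_i) and m_i with a per-sample mixing factor m_i drawn from a
bimodal distribution — a case-vs-control design.  Between-sample variation
mimics real spectra: a shared per-sample ppm shift, independent per-line
jitter, and additive Gaussian noise.  Both default templates deliberately
share two lines at identical positions with identical areas, so those
positions carry no group information (the "peak composition" confound),
while every template-specific line discriminates the groups.

All randomness flows through one seeded generator in a fixed draw order, so
a config with the shift and jitter widths set to zero re-uses the *same*
mixing factors and noise realisation — an oracle "perfectly aligned"
version of the same dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra_io import SpectraSet


@dataclass
class MetaboliteTemplate:
    """A metabolite as a list of (center_ppm, relative_area, width_ppm) lines."""

    name: str
    peaks: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        for c, a, w in self.peaks:
            if a <= 0 or w <= 0:
                raise ValueError(f"{self.name}: areas and widths must be > 0")


#: two phenolic-acid-like templates: an aliphatic CH2 singlet, an aromatic
#: multiplet region, and two deliberately coincident lines (6.78, 4.70 ppm)
DEFAULT_TEMPLATE_A = MetaboliteTemplate(
    "metabolite_a",
    [
        (2.50, 0.6, 0.006),
        (3.45, 2.0, 0.006),
        (4.70, 1.5, 0.006),
        (6.78, 1.0, 0.006),
        (6.86, 1.0, 0.006),
        (7.24, 1.0, 0.006),
    ],
)
DEFAULT_TEMPLATE_B = MetaboliteTemplate(
    "metabolite_b",
    [
        (1.33, 0.8, 0.006),
        (3.40, 2.0, 0.006),
        (4.70, 1.5, 0.006),
        (6.72, 1.0, 0.006),
        (6.78, 1.0, 0.006),
        (6.90, 1.0, 0.006),
    ],
)


@dataclass
class SimConfig:
    """Study conditions of the simulated case-vs-control dataset.

    ``mixing`` holds two (mean, sd, weight) modes for m_i in [0, 1];
    ``amplitude_scale`` sets absolute intensities (defaults keep apexes far
    above the default raw-intensity detection floor of 1000);
    ``noise_sd`` is the additive Gaussian noise level in intensity units.
    """

    n_spectra: int = 20
    axis: tuple[float, float, int] = (0.0, 10.0, 4096)  # (ppm_min, ppm_max, P)
    template_a: MetaboliteTemplate = field(default_factory=lambda: DEFAULT_TEMPLATE_A)
    template_b: MetaboliteTemplate = field(default_factory=lambda: DEFAULT_TEMPLATE_B)
    mixing: tuple[tuple[float, float, float], ...] = ((0.25, 0.08, 0.5), (0.75, 0.08, 0.5))
    global_shift_sd: float = 0.005  # ppm, shared by all lines of a sample
    per_peak_jitter_sd: float = 0.001  # ppm, independent per line
    noise_sd: float = 2000.0
    amplitude_scale: float = 2.0e4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, p = self.axis
        if p < 1024:
            raise ValueError("axis must have at least 1024 points")
        if hi <= lo:
            raise ValueError("axis ppm_max must exceed ppm_min")
        for mean, sd, w in self.mixing:
            if not 0.0 <= mean <= 1.0:
                raise ValueError("mixing mode means must lie in [0, 1]")
            if sd < 0 or w < 0:
                raise ValueError("mixing sds and weights must be >= 0")
        for t in (self.template_a, self.template_b):
            for c, _, _ in t.peaks:
                if not lo < c < hi:
                    raise ValueError(f"{t.name}: line at {c} ppm outside the axis")

    def aligned(self) -> "SimConfig":
        """Same dataset with shift and jitter switched off (oracle alignment)."""
        return replace(self, global_shift_sd=0.0, per_peak_jitter_sd=0.0)


@dataclass
class SimTruth:
    """Planted ground truth of one simulated dataset."""

    peaks: pd.DataFrame  # per (sample, line): positions, areas
    mixing: pd.DataFrame  # sample_id, m, group
    lines: pd.DataFrame  # unique line positions with discriminating flag

    @property
    def discriminating_ppm(self) -> np.ndarray:
        return self.lines.loc[self.lines["discriminating"], "ppm"].to_numpy()


def _lorentzian(x: np.ndarray, center: float, area: float, gamma: float) -> np.ndarray:
    return (area / np.pi) * gamma / ((x - center) ** 2 + gamma**2)


def _truth_lines(cfg: SimConfig, ppm: np.ndarray) -> pd.DataFrame:
    """Merge template lines closer than 3 measurement points into one
    position and decide which positions discriminate the two groups."""
    step = (cfg.axis[1] - cfg.axis[0]) / (cfg.axis[2] - 1)
    entries = []
    for t, which in ((cfg.template_a, "a"), (cfg.template_b, "b")):
        for c, a, w in t.peaks:
            entries.append((c, which, a))
    entries.sort()
    merged: list[list] = []  # [ppm_sum, n, area_a, area_b]
    for c, which, a in entries:
        if merged and abs(c - merged[-1][0] / merged[-1][1]) <= 3 * step:
            merged[-1][0] += c
            merged[-1][1] += 1
            merged[-1][2 if which == "a" else 3] += a
        else:
            merged.append([c, 1, a if which == "a" else 0.0, 0.0 if which == "a" else a])
    rows = []
    for s, n, aa, ab in merged:
        c = s / n
        idx = int(np.abs(ppm - c).argmin())
        rel = abs(ab - aa) / (aa + ab)
        rows.append((c, idx, aa, ab, ab - aa, rel > 0.05))
    return pd.DataFrame(
        rows, columns=["ppm", "index", "area_a", "area_b", "effect", "discriminating"]
    )


def simulate_spectra(cfg: SimConfig | None = None) -> tuple[SpectraSet, SimTruth]:
    """Render the simulated dataset; bit-identical for a given config."""
    cfg = cfg or SimConfig()
    lo, hi, p = cfg.axis
    ppm = np.linspace(hi, lo, p)  # stored convention: ppm descending
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_spectra

    means = np.array([m for m, _, _ in cfg.mixing])
    sds = np.array([s for _, s, _ in cfg.mixing])
    weights = np.array([w for _, _, w in cfg.mixing], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(cfg.mixing), size=n, p=weights)
    m = np.clip(means[comp] + sds[comp] * rng.standard_normal(n), 0.0, 1.0)

    lines = [(t, c, a, w) for t, tpl in (("a", cfg.template_a), ("b", cfg.template_b)) for c, a, w in tpl.peaks]
    shifts = cfg.global_shift_sd * rng.standard_normal(n)
    jitter = cfg.per_peak_jitter_sd * rng.standard_normal((n, len(lines)))
    noise = cfg.noise_sd * rng.standard_normal((n, p))

    sample_ids = [f"sim{i:02d}" for i in range(n)]
    intensities = np.empty((n, p))
    truth_rows = []
    for i in range(n):
        spec = np.zeros(p)
        for k, (which, c, a, w) in enumerate(lines):
            weight = (1.0 - m[i]) if which == "a" else m[i]
            area = cfg.amplitude_scale * weight * a
            if area <= 0:
                continue
            pos = c + shifts[i] + jitter[i, k]
            spec += _lorentzian(ppm, pos, area, w)
            truth_rows.append(
                (
                    sample_ids[i],
                    which,
                    k,
                    c,
                    pos,
                    int(np.abs(ppm - pos).argmin()),
                    area,
                    w,
                )
            )
        intensities[i] = spec + noise[i]

    spectra = SpectraSet(
        ppm=ppm,
        intensities=intensities,
        sample_ids=sample_ids,
        response=comp.astype(float),
    )
    truth = SimTruth(
        peaks=pd.DataFrame(
            truth_rows,
            columns=[
                "sample_id",
                "template",
                "line_id",
                "center_ppm",
                "actual_ppm",
                "index",
                "area",
                "width_ppm",
            ],
        ),
        mixing=pd.DataFrame({"sample_id": sample_ids, "m": m, "group": comp}),
        lines=_truth_lines(cfg, ppm),
    )
    return spectra, truth
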
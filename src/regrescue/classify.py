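"""Consensus binding sites across replicates and lost/rescued/enhanced classification.

The experiment is a 2x2 condition design: background (empty vector EV vs
HES6 overexpression) crossed with treatment (vehicle vs the anti-androgen
bicalutamide).  Replicate peak calls are consolidated by single-linkage
overlap merging across all samples; a site is deemed present in a condition
when a sufficient fraction of that condition's replicates called it.  Sites
present at baseline (EV-vehicle) are then classified by their behaviour under
androgen inhibition:

* **lost** — absent in both EV-bicalutamide and HES6-bicalutamide;
* **rescued** — absent in EV-bicalutamide but present in HES6-bicalutamide;
* **enhanced** — retained in EV-bicalutamide with HES6-bicalutamide signal at
  least ``enhancement_fold_min`` times the EV-bicalutamide signal;
* **other** — everything else (including sites absent at baseline).

HES6-vehicle presence is recorded but not consulted by the classifier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .intervals import Interval, SignalTrack, rpm

__all__ = [
    "Condition",
    "EV_VEHICLE",
    "EV_BIC",
    "HES6_VEHICLE",
    "HES6_BIC",
    "CONDITIONS",
    "Peak",
    "PeakSet",
    "ClassificationConfig",
    "ConsensusSite",
    "SiteClass",
    "consolidate_replicates",
    "site_signal",
    "classify_site",
    "classify_sites",
    "class_sets",
]

BACKGROUNDS = ("EV", "HES6")
TREATMENTS = ("vehicle", "bicalutamide")


@dataclass(frozen=True, order=True)
class Condition:
    background: str
    treatment: str

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise ValueError(f"background must be one of {BACKGROUNDS}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")

    @property
    def label(self) -> str:
        return f"{self.background}.{self.treatment}"

    @classmethod
    def parse(cls, label: str) -> "Condition":
        background, treatment = label.split(".")
        return cls(background, treatment)


EV_VEHICLE = Condition("EV", "vehicle")
EV_BIC = Condition("EV", "bicalutamide")
HES6_VEHICLE = Condition("HES6", "vehicle")
HES6_BIC = Condition("HES6", "bicalutamide")
#: The four cells of the 2x2 design, in canonical order.
CONDITIONS = (EV_VEHICLE, EV_BIC, HES6_VEHICLE, HES6_BIC)


@dataclass(frozen=True)
class Peak:
    """One replicate-level peak call with an absolute summit position."""

    interval: Interval
    summit: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(f"summit {self.summit} outside {self.interval}")


@dataclass
class PeakSet:
    condition: Condition
    replicate: int
    peaks: list[Peak]


@dataclass
class ClassificationConfig:
    """Thresholds behind "highly reproducible" and "clearly enhanced".

    ``reproducibility_min_fraction`` — fraction of a condition's replicates
    that must call a site for it to count as present; the default 0.5
    (majority rule) tolerates realistic per-replicate drop-out, and 0.75
    (3 of 4) is a stricter alternative.
    ``merge_max_gap`` — bp gap tolerated when single-linkage merging replicate
    peaks (0 = overlap or abutment required).
    ``summit_window_half_width`` — half-width (bp) of the summit-centred
    window over which mean RPM signal is measured.
    ``enhancement_fold_min`` — minimum HES6-bic / EV-bic mean-RPM fold for a
    retained site to count as enhanced.
    """

    reproducibility_min_fraction: float = 0.5
    merge_max_gap: int = 0
    summit_window_half_width: int = 250
    enhancement_fold_min: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.reproducibility_min_fraction <= 1):
            raise ValueError("reproducibility_min_fraction must be in (0, 1]")
        if self.merge_max_gap < 0:
            raise ValueError("merge_max_gap must be >= 0")
        if self.summit_window_half_width <= 0:
            raise ValueError("summit_window_half_width must be positive")
        if self.enhancement_fold_min <= 1:
            raise ValueError("enhancement_fold_min must exceed 1")


class SiteClass(enum.Enum):
    LOST = "lost"
    RESCUED = "rescued"
    ENHANCED = "enhanced"
    OTHER = "other"


@dataclass
class ConsensusSite:
    """A replicate-averaged binding site.

    ``summit`` is the rounded arithmetic mean of contributing replicate
    summits; ``support[c]`` the fraction of condition-c replicates that
    called the site; ``present[c]`` is ``support[c] >= threshold``;
    ``signal[c]`` the mean RPM in the summit window (filled by
    :func:`site_signal`).
    """

    interval: Interval
    summit: int
    support: dict[Condition, float]
    present: dict[Condition, bool]
    signal: dict[Condition, float] = field(default_factory=dict)
    site_class: SiteClass | None = None
    site_id: str = ""


def consolidate_replicates(
    peak_sets: list[PeakSet], config: ClassificationConfig | None = None
) -> list[ConsensusSite]:
    """Group replicate peaks into consensus sites (single-linkage overlap).

    Every condition of the 2x2 design must be represented by at least one
    replicate.  The consensus interval is the union span of contributing
    peaks; output order is genomic and independent of the input ordering of
    peak sets or of peaks within a set.
    """
    config = config or ClassificationConfig()
    n_reps = {c: set() for c in CONDITIONS}
    for ps in peak_sets:
        n_reps[ps.condition].add(ps.replicate)
    missing = [c.label for c in CONDITIONS if not n_reps[c]]
    if missing:
        raise ValueError(f"no replicates for condition(s): {missing}")

    tagged: list[tuple[Peak, Condition, int]] = []
    for ps in peak_sets:
        for p in ps.peaks:
            tagged.append((p, ps.condition, ps.replicate))
    tagged.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.start, t[0].interval.end))

    sites: list[ConsensusSite] = []
    cluster: list[tuple[Peak, Condition, int]] = []

    def flush() -> None:
        if not cluster:
            return
        chrom = cluster[0][0].interval.chrom
        start = min(p.interval.start for p, _, _ in cluster)
        end = max(p.interval.end for p, _, _ in cluster)
        summit = int(round(float(np.mean([p.summit for p, _, _ in cluster]))))
        support = {}
        for c in CONDITIONS:
            reps = {r for _, cc, r in cluster if cc == c}
            support[c] = len(reps) / len(n_reps[c])
        present = {c: support[c] >= config.reproducibility_min_fraction for c in CONDITIONS}
        sites.append(ConsensusSite(Interval(chrom, start, end), summit, support, present))

    cur_chrom, cur_end = None, -1
    for item in tagged:
        iv = item[0].interval
        if iv.chrom == cur_chrom and iv.start <= cur_end + config.merge_max_gap:
            cluster.append(item)
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            cluster = [item]
            cur_chrom, cur_end = iv.chrom, iv.end
    flush()
    for i, s in enumerate(sites):
        s.site_id = f"site{i + 1:05d}"
    return sites


def site_signal(
    site: ConsensusSite,
    tracks: dict[Condition, list[SignalTrack]],
    config: ClassificationConfig | None = None,
) -> dict[Condition, float]:
    """Mean RPM per condition in the summit window, averaged over replicates."""
    config = config or ClassificationConfig()
    hw = config.summit_window_half_width
    out: dict[Condition, float] = {}
    for c in CONDITIONS:
        reps = tracks.get(c)
        if not reps:
            raise ValueError(f"no signal tracks for condition {c.label}")
        vals = [
            rpm(t.counts(site.interval.chrom, site.summit - hw, site.summit + hw), t.library_size)
            for t in reps
        ]
        out[c] = float(np.mean(vals))
    site.signal = out
    return out


def classify_site(site: ConsensusSite, config: ClassificationConfig | None = None) -> SiteClass:
    """Assign exactly one class to a consensus site (see module docstring)."""
    config = config or ClassificationConfig()
    if not site.present[EV_VEHICLE]:
        return SiteClass.OTHER
    if not site.present[EV_BIC]:
        if site.present[HES6_BIC]:
            return SiteClass.RESCUED
        return SiteClass.LOST
    # retained under inhibition: enhanced iff the HES6-bic signal fold is met
    ev = site.signal.get(EV_BIC)
    h6 = site.signal.get(HES6_BIC)
    if ev is None or h6 is None:
        raise ValueError(f"site {site.site_id}: signal required to test enhancement")
    if (ev > 0 and h6 >= config.enhancement_fold_min * ev) or (ev == 0 and h6 > 0):
        return SiteClass.ENHANCED
    return SiteClass.OTHER


def classify_sites(
    sites: list[ConsensusSite], config: ClassificationConfig | None = None
) -> list[ConsensusSite]:
    for s in sites:
        s.site_class = classify_site(s, config)
    return sites


def class_sets(sites: list[ConsensusSite]) -> dict[SiteClass, list[Interval]]:
    """Partition classified sites into per-class interval lists (all classes keyed)."""
    out: dict[SiteClass, list[Interval]] = {cls: [] for cls in SiteClass}
    for s in sites:
        if s.site_class is None:
            raise ValueError(f"site {s.site_id} not classified")
        out[s.site_class].append(s.interval)
    return out
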
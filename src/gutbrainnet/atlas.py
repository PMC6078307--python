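"""Brain parcellation tables for the synthetic cohorts.

The full-size atlas mirrors a Destrieux-style whole-brain parcellation:
74 cortical labels per hemisphere, 7 subcortical structures per
hemisphere, one cerebellar label per hemisphere, and a midline brain
stem — 165 regions in total.  Only the twelve extended-reward regions
of interest carry anatomical names (nucleus accumbens, amygdala, and
the four anterior-insula substructures, per hemisphere); the remaining
cortical labels are synthetic fillers, which is all the downstream
graph construction needs.

Region labels follow ``{hemisphere}_{structure}`` for named structures
(``L_NAcc``, ``R_ALSVerp``) and ``ctx_{hemisphere}_{index}`` for filler
cortex.  Volumes are arbitrary units, drawn once per atlas seed and
held fixed across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: anterior-insula substructures (cortical, per hemisphere):
#: short insular gyrus, anterior segment of the circular sulcus of the
#: insula, and the horizontal / vertical rami of the anterior segment
#: of the lateral sulcus.
AINS_STRUCTURES = ("ShoInG", "ACirInS", "ALSHorp", "ALSVerp")

#: subcortical regions of interest: nucleus accumbens and amygdala.
SUBCORTICAL_ROIS = ("NAcc", "Amg")

#: non-ROI subcortical structures completing the 7 per hemisphere.
SUBCORTICAL_OTHER = ("Thal", "Caud", "Put", "Pall", "Hipp")

#: ROI structures: 6 per hemisphere, 12 nodes total.
ROI_STRUCTURES = SUBCORTICAL_ROIS + AINS_STRUCTURES

N_CORTICAL_PER_HEMI = 74
N_SUBCORTICAL_PER_HEMI = 7
DEFAULT_N_REGIONS = 165  # 74*2 + 7*2 + 2 cerebellar + brain stem

HEMISPHERES = ("L", "R")


def roi_labels() -> list[str]:
    """The 12 extended-reward ROI labels in canonical order."""
    return [f"{h}_{s}" for h in HEMISPHERES for s in ROI_STRUCTURES]


def _volume(rng: np.random.Generator, kind: str) -> float:
    # lognormal around plausible relative sizes (arbitrary units)
    scale = {"cortical": 4000.0, "subcortical": 1200.0,
             "cerebellum": 15000.0, "brainstem": 20000.0}[kind]
    return float(scale * rng.lognormal(mean=0.0, sigma=0.25))


def make_parcellation(n_regions: int = DEFAULT_N_REGIONS,
                      seed: int = 0) -> pd.DataFrame:
    """Build the region table.

    Parameters
    ----------
    n_regions : int
        Total node count.  The default 165 reproduces the full atlas
        composition; smaller values (>= 13) keep the 12 ROIs plus the
        brain stem and fill the remainder with synthetic cortex,
        balanced across hemispheres.
    seed : int
        Seeds the (fixed) volume draw.

    Returns
    -------
    pandas.DataFrame with columns ``label``, ``hemisphere`` (L/R/M),
    ``volume`` (arbitrary units, > 0) and ``is_roi``.
    """
    if n_regions < 13:
        raise ValueError(
            f"n_regions must be >= 13 to hold the 12 ROIs plus the brain "
            f"stem; got {n_regions}")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def add(label: str, hemi: str, kind: str, is_roi: bool) -> None:
        rows.append({"label": label, "hemisphere": hemi,
                     "volume": _volume(rng, kind), "is_roi": is_roi})

    if n_regions == DEFAULT_N_REGIONS:
        for hemi in HEMISPHERES:
            for s in AINS_STRUCTURES:
                add(f"{hemi}_{s}", hemi, "cortical", True)
            n_fill = N_CORTICAL_PER_HEMI - len(AINS_STRUCTURES)
            for i in range(n_fill):
                add(f"ctx_{hemi}_{i:03d}", hemi, "cortical", False)
            for s in SUBCORTICAL_ROIS:
                add(f"{hemi}_{s}", hemi, "subcortical", True)
            for s in SUBCORTICAL_OTHER:
                add(f"{hemi}_{s}", hemi, "subcortical", False)
            add(f"{hemi}_Cbm", hemi, "cerebellum", False)
        add("M_BStem", "M", "brainstem", False)
    else:
        for hemi in HEMISPHERES:
            for s in AINS_STRUCTURES:
                add(f"{hemi}_{s}", hemi, "cortical", True)
            for s in SUBCORTICAL_ROIS:
                add(f"{hemi}_{s}", hemi, "subcortical", True)
        n_fill = n_regions - len(rows) - 1
        for i in range(n_fill):
            hemi = HEMISPHERES[i % 2]
            add(f"ctx_{hemi}_{i // 2:03d}", hemi, "cortical", False)
        add("M_BStem", "M", "brainstem", False)

    regions = pd.DataFrame(rows)
    assert len(regions) == n_regions
    assert regions["label"].is_unique
    return regions


def validate_regions(regions: pd.DataFrame) -> None:
    """Check the RegionInfo invariants (unique labels, positive volumes)."""
    required = {"label", "hemisphere", "volume", "is_roi"}
    missing = required - set(regions.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    if not regions["label"].is_unique:
        raise ValueError("region labels must be unique")
    if (regions["volume"] <= 0).any():
        raise ValueError("region volumes must be strictly positive")
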
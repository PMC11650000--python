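"""Default 68-region cortical parcellation (34 regions per hemisphere).

The region list uses the 68 Desikan–Killiany-style cortical labels. Within
each hemisphere the labels are ordered roughly anterior to posterior; the
default alpha-amplitude topography tapers linearly over that ordering so
occipital/parietal regions carry the strongest alpha, matching the
posterior-dominant topography of the resting alpha rhythm.
"""

from __future__ import annotations

import numpy as np

# 34 cortical labels per hemisphere, ordered approximately anterior -> posterior.
_DK_LABELS_A2P = [
    "frontalpole",
    "parsorbitalis",
    "lateralorbitofrontal",
    "medialorbitofrontal",
    "parstriangularis",
    "rostralanteriorcingulate",
    "parsopercularis",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "insula",
    "temporalpole",
    "entorhinal",
    "precentral",
    "paracentral",
    "transversetemporal",
    "superiortemporal",
    "middletemporal",
    "parahippocampal",
    "inferiortemporal",
    "postcentral",
    "posteriorcingulate",
    "supramarginal",
    "fusiform",
    "isthmuscingulate",
    "superiorparietal",
    "inferiorparietal",
    "precuneus",
    "bankssts",
    "lingual",
    "pericalcarine",
    "cuneus",
    "lateraloccipital",
]

N_REGIONS = 68
N_PER_HEMISPHERE = 34


def default_region_labels() -> list[str]:
    """68 region labels: left-hemisphere block first, then right."""
    return [f"lh_{name}" for name in _DK_LABELS_A2P] + [
        f"rh_{name}" for name in _DK_LABELS_A2P
    ]


def default_hemispheres() -> list[str]:
    """Per-region hemisphere assignment matching :func:`default_region_labels`."""
    return ["left"] * N_PER_HEMISPHERE + ["right"] * N_PER_HEMISPHERE


def default_topography(
    n_regions: int = N_REGIONS,
    posterior_weight: float = 1.0,
    anterior_weight: float = 0.4,
) -> np.ndarray:
    """Posterior-dominant alpha amplitude weights.

    Weights taper linearly from ``anterior_weight`` at the front of each
    hemisphere's anterior->posterior label ordering to ``posterior_weight``
    at the back. For 68 regions the taper is applied per 34-region
    hemisphere block; for other even region counts, per half.
    """
    if n_regions < 2 or n_regions % 2:
        raise ValueError(f"n_regions must be even and >= 2, got {n_regions}")
    half = n_regions // 2
    ramp = np.linspace(anterior_weight, posterior_weight, half)
    return np.concatenate([ramp, ramp])
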
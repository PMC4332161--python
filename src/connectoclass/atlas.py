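"""Bilateral cortical parcellation used to label connectome nodes.

The 68 network nodes are the 34 Desikan-Killiany cortical regions per
hemisphere.  Node order is fixed: the full left-hemisphere block first, then
the right-hemisphere block, each in the canonical region order below.  Every
connectivity matrix in the package shares this ordering.
"""

from __future__ import annotations

# Canonical order of the 34 base cortical regions (one hemisphere).
BASE_REGIONS: tuple[str, ...] = (
    "banks of the superior temporal sulcus",
    "caudal anterior cingulate",
    "caudal middle frontal",
    "cuneus",
    "entorhinal",
    "frontal pole",
    "fusiform",
    "inferior parietal",
    "inferior temporal",
    "insula",
    "isthmus of the cingulate",
    "lateral occipital",
    "lateral orbitofrontal",
    "lingual",
    "medial orbitofrontal",
    "middle temporal",
    "parahippocampal",
    "paracentral",
    "pars opercularis",
    "pars orbitalis",
    "pars triangularis",
    "peri-calcarine",
    "postcentral",
    "posterior cingulate",
    "precentral",
    "precuneus",
    "rostral anterior cingulate",
    "rostral middle frontal",
    "superior frontal",
    "superior parietal",
    "superior temporal",
    "supra-marginal",
    "temporal pole",
    "transverse temporal",
)

N_REGIONS = 2 * len(BASE_REGIONS)


def region_atlas() -> list[str]:
    """Return the fixed 68-label atlas, left-hemisphere block first.

    Labels read e.g. ``"Left rostral anterior cingulate"``,
    ``"Right pars orbitalis"``.
    """
    return [f"{hemi} {name}" for hemi in ("Left", "Right") for name in BASE_REGIONS]


def region_index(name: str) -> int:
    """0-based node index of a region label in the fixed atlas order."""
    labels = region_atlas()
    try:
        return labels.index(name)
    except ValueError:
        raise KeyError(f"unknown region label: {name!r}") from None
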
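"""Cortical parcellation constants.

The Desikan-Killiany scheme divides each hemisphere into 34 gyral
regions; the names below follow the FreeSurfer ``aparc`` labels.
"""

DESIKAN_KILLIANY = [
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
]


def region_names(n_regions: int) -> list[str]:
    """Region names for a parcellation of ``n_regions`` regions.

    The 34-region case uses the Desikan-Killiany names; any other count
    falls back to generic zero-padded names.
    """
    if n_regions == len(DESIKAN_KILLIANY):
        return list(DESIKAN_KILLIANY)
    return [f"region{i:03d}" for i in range(1, n_regions + 1)]
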
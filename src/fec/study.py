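"""Design constants of the published wheat stem-endophyte survey.

A field survey of stem endophytic fungi in domesticated bread wheat
(*Triticum aestivum*, TA) and two wild relatives — *Aegilops sharonensis*
(AS) and *Triticum dicoccoides* (TD) — sampled from paired wild/field sites
in Israel.  The tables below record the sampling design (collected plants
and samples retained after quality filtering, per population) and the
published among-population differentiation summaries (effective numbers of
populations), which serve as worked examples for the effective-number
normalization identity.
"""

from __future__ import annotations

#: host -> site -> (samples retained for analysis, plants collected)
SAMPLING_DESIGN: dict[str, dict[str, tuple[int, int]]] = {
    "AS": {
        "ArsufGaash": (29, 44),
        "Zikkim": (41, 42),
        "Palmachim": (37, 40),
        "Netanya": (43, 44),
    },
    "TD": {
        "Almagor": (34, 42),
        "Eliad": (37, 42),
        "RamotMenache": (44, 44),
    },
    "TA": {
        "ArsufGaash": (37, 42),
        "Palmachim": (42, 43),
        "Almagor": (30, 43),
        "Eliad": (39, 44),
        "RamotMenache": (42, 42),
        "Karmiya": (34, 42),
        "HaderaElyachin": (41, 42),
    },
}

#: Taxon bookkeeping of the survey: taxa after removing singletons and
#: doubletons, taxa failing the prevalence (incidence < 5) filter, and the
#: retained core set.
TAXA_AFTER_SINGLETON_DOUBLETON = 1666
TAXA_BELOW_PREVALENCE = 1001
CORE_TAXA = 665

#: Published among-population differentiation for incidence (Dice) and
#: abundance (Hellinger/Bray-Curtis) data: host -> (number of populations N,
#: differentiation D, effective number of populations 1D(TM), normalized
#: 1nD(TM)).
DIFFERENTIATION_INCIDENCE: dict[str, tuple[int, float, float, float]] = {
    "AS": (4, 0.125, 2.637, 0.546),
    "TA": (7, 0.190, 4.251, 0.542),
    "TD": (3, 0.151, 2.093, 0.547),
}

DIFFERENTIATION_ABUNDANCE: dict[str, tuple[int, float, float, float]] = {
    "AS": (4, 0.314, 2.138, 0.379),
    "TA": (7, 0.367, 3.200, 0.367),
    "TD": (3, 0.288, 1.749, 0.375),
}


def retained_samples_total() -> int:
    """Total samples used in the survey's statistical analyses."""
    return sum(r for sites in SAMPLING_DESIGN.values() for r, _ in sites.values())


def collected_plants_total() -> int:
    """Total plants collected (sequencing libraries prepared)."""
    return sum(c for sites in SAMPLING_DESIGN.values() for _, c in sites.values())
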
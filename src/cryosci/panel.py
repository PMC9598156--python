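"""Reference plasma cytokine/chemokine panel of the rat spinal-cord cryoinjury study.

Twenty-one analytes were measured in plasma 12 h after a controlled cryogenic
spinal-cord lesion, in intact animals (n = 5) and in injured animals later
assigned — by their treadmill recovery dynamics — to a favorable (n = 8) or
adverse (n = 8) outcome group.  The study reports each analyte per group as
median [minimum; maximum] in pg/mL; those summaries are reproduced here and
are the anchor for the synthetic cohort generator (:mod:`cryosci.synth`),
which pins the corresponding order statistics exactly.
"""

from __future__ import annotations

from .synth import AnalyteDistributionSpec

#: Animals per outcome group in the reference study.
GROUP_SIZES: dict[str, int] = {"intact": 5, "favorable": 8, "adverse": 8}

#: Functional class of each analyte, for report grouping only.
ANALYTE_CLASSES: dict[str, str] = {
    "IL-1α": "proinflammatory cytokine",
    "IL-1β": "proinflammatory cytokine",
    "IL-6": "proinflammatory cytokine",
    "TNFα": "proinflammatory cytokine",
    "IL-17A": "proinflammatory cytokine",
    "IFNγ": "proinflammatory cytokine",
    "IL-12p70": "proinflammatory cytokine",
    "IL-18": "proinflammatory cytokine",
    "GRO/KC": "chemokine",
    "MCP-1": "chemokine",
    "MIP-1α": "chemokine",
    "MIP-2": "chemokine",
    "RANTES": "chemokine",
    "G-CSF": "proliferation factor",
    "GM-CSF": "proliferation factor",
    "IL-2": "proliferation factor",
    "IL-5": "proliferation factor",
    "VEGF": "proliferation factor",
    "IL-4": "anti-inflammatory cytokine",
    "IL-13": "anti-inflammatory cytokine",
    "IL-10": "anti-inflammatory cytokine",
}

# analyte -> group -> (median, minimum, maximum), all pg/mL.
REFERENCE_PANEL: dict[str, dict[str, tuple[float, float, float]]] = {
    "IL-1α": {
        "intact": (4.0, 1.5, 7.5),
        "favorable": (28.8, 14.5, 42.0),
        "adverse": (427.5, 221.5, 605.5),
    },
    "IL-1β": {
        "intact": (33.5, 17.5, 50.5),
        "favorable": (17.0, 10.0, 25.0),
        "adverse": (451.5, 413.0, 491.0),
    },
    "IL-6": {
        "intact": (5.5, 2.0, 9.0),
        "favorable": (15.0, 2.0, 27.0),
        "adverse": (288.0, 15.0, 598.0),
    },
    "TNFα": {
        "intact": (142.5, 32.0, 251.5),
        "favorable": (16.0, 6.0, 23.0),
        "adverse": (375.0, 318.0, 422.0),
    },
    "IL-17A": {
        "intact": (140.5, 58.5, 210.5),
        "favorable": (46.5, 43.0, 52.5),
        "adverse": (341.5, 18.0, 685.5),
    },
    "IFNγ": {
        "intact": (20.0, 13.0, 24.0),
        "favorable": (18.5, 7.0, 30.5),
        "adverse": (355.0, 118.0, 658.0),
    },
    "IL-12p70": {
        "intact": (0.5, 0.0, 1.0),
        "favorable": (30.0, 7.0, 53.0),
        "adverse": (330.5, 23.0, 682.0),
    },
    "IL-18": {
        "intact": (366.0, 247.0, 518.0),
        "favorable": (118.8, 49.5, 192.0),
        "adverse": (430.5, 157.0, 794.0),
    },
    "GRO/KC": {
        "intact": (5.5, 2.5, 11.5),
        "favorable": (52.5, 42.0, 62.0),
        "adverse": (525.5, 137.0, 993.5),
    },
    "MCP-1": {
        "intact": (1.2, 0.9, 2.0),
        "favorable": (196.0, 114.0, 294.0),
        "adverse": (715.5, 105.5, 1402.5),
    },
    "MIP-1α": {
        "intact": (3.0, 1.0, 5.0),
        "favorable": (52.8, 50.5, 55.0),
        "adverse": (386.0, 35.0, 712.5),
    },
    "MIP-2": {
        "intact": (44.0, 6.5, 64.5),
        "favorable": (99.5, 95.0, 108.0),
        "adverse": (94.0, 63.0, 124.0),
    },
    "RANTES": {
        "intact": (66.5, 47.0, 89.5),
        "favorable": (467.5, 249.0, 688.0),
        "adverse": (2147.5, 250.0, 4598.0),
    },
    "G-CSF": {
        "intact": (7.0, 3.0, 13.0),
        "favorable": (62.0, 51.0, 75.0),
        "adverse": (416.0, 126.5, 734.0),
    },
    "GM-CSF": {
        "intact": (389.0, 294.0, 522.0),
        "favorable": (35.0, 8.0, 53.0),
        "adverse": (369.0, 124.0, 664.0),
    },
    "IL-2": {
        "intact": (16.5, 1.5, 26.0),
        "favorable": (22.5, 11.0, 34.5),
        "adverse": (191.0, 23.5, 401.0),
    },
    "IL-5": {
        "intact": (34.5, 6.5, 57.5),
        "favorable": (21.0, 10.0, 30.5),
        "adverse": (308.0, 12.0, 619.0),
    },
    "VEGF": {
        "intact": (12.0, 10.0, 17.0),
        "favorable": (58.5, 48.5, 65.0),
        "adverse": (284.5, 26.0, 559.0),
    },
    "IL-4": {
        "intact": (1.5, 0.5, 3.5),
        "favorable": (23.0, 12.5, 35.0),
        "adverse": (314.5, 18.0, 618.0),
    },
    "IL-13": {
        "intact": (14.5, 2.5, 20.5),
        "favorable": (16.5, 3.0, 29.0),
        "adverse": (301.0, 177.5, 424.0),
    },
    "IL-10": {
        "intact": (6.0, 4.0, 16.0),
        "favorable": (33.0, 16.0, 49.0),
        "adverse": (324.0, 32.0, 640.0),
    },
}

#: All analyte names in panel order.
ANALYTES: tuple[str, ...] = tuple(REFERENCE_PANEL)


def reference_specs(
    analytes: "list[str] | None" = None,
    groups: "list[str] | None" = None,
) -> list[AnalyteDistributionSpec]:
    """Distribution specs for the reference panel.

    Parameters
    ----------
    analytes, groups
        Optional subsets; defaults are the full 21-analyte panel and all
        three outcome groups.
    """
    analytes = list(ANALYTES) if analytes is None else list(analytes)
    groups = list(GROUP_SIZES) if groups is None else list(groups)
    specs = []
    for analyte in analytes:
        try:
            per_group = REFERENCE_PANEL[analyte]
        except KeyError:
            raise KeyError(f"unknown analyte {analyte!r}") from None
        for group in groups:
            median, minimum, maximum = per_group[group]
            specs.append(
                AnalyteDistributionSpec(
                    analyte=analyte,
                    group=group,
                    median=median,
                    minimum=minimum,
                    maximum=maximum,
                    n=GROUP_SIZES[group],
                )
            )
    return specs
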
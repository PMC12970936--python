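"""The default 27-mediator sputum panel and its biological-function subsets.

Twenty-one members belong to one of three functional subsets (inflammatory,
chemotactic, proteases/enzymes); the remainder are additional panel analytes
measured alongside them (protease inhibitors and broad immune cytokines).
"""

INFLAMMATORY = (
    "IL-1a",
    "IL-1b",
    "IL-8",
    "TNF-a",
    "IL-10",
    "IL12p70",
    "CRP",
)

CHEMOTACTIC = (
    "Eotaxin",
    "Eotaxin-3",
    "IL12p40",
    "IP-10",
    "MCP-1",
    "MIP-1a",
    "MIP-1b",
    "TARC",
    "sICAM1",
    "sVCAM1",
)

PROTEASES_ENZYMES = (
    "MMP-2",
    "MMP-9",
    "MPO",
    "NE",
)

#: Panel analytes outside the three functional subsets.
OTHER = (
    "TIMP-1",
    "TIMP-2",
    "IL-6",
    "IL-4",
    "IL-13",
    "IFN-g",
)

#: The full 27-mediator panel, in a fixed canonical order.
PANEL = INFLAMMATORY + CHEMOTACTIC + PROTEASES_ENZYMES + OTHER

assert len(PANEL) == 27
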
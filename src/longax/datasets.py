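"""Census of the whole-brain axon reconstruction datasets behind this workflow.

The workflow was developed against three sources of mouse whole-brain
axonal reconstructions (one public single-neuron reconstruction project,
one published whole-brain imaging dataset, and a further set acquired with
the same protocol as the latter).  The tables below record the published
bookkeeping of those inputs: how many morphologies each source contributed,
how many were excluded by sanitization or by the projection analysis, and
how many axons per isocortex source region entered cluster fitting for the
cortex-wide synthesis.  They let the totals be recomputed from their parts.
"""

from __future__ import annotations

__all__ = [
    "SOURCE_DATASET_SIZES",
    "EXCLUDED_BY_REPAIR",
    "EXCLUDED_BY_PROJECTION_ANALYSIS",
    "ISOCORTEX_INPUT_AXON_COUNTS",
    "total_used_morphologies",
    "total_isocortex_input_axons",
]

# morphologies contributed per source dataset
SOURCE_DATASET_SIZES: dict[str, int] = {
    "single_neuron_project": 1084,
    "whole_brain_imaging": 1741,
    "whole_brain_imaging_new": 800,
}

# exclusions: failed sanitization (per source) and failed projection
# analysis (out of bounds or faulty axons, per source)
EXCLUDED_BY_REPAIR: dict[str, int] = {
    "single_neuron_project": 8,
    "whole_brain_imaging": 8,
    "whole_brain_imaging_new": 0,
}
EXCLUDED_BY_PROJECTION_ANALYSIS: dict[str, int] = {
    "single_neuron_project": 1,
    "whole_brain_imaging": 5,
    "whole_brain_imaging_new": 2,
}

# axons entering cluster fitting, per isocortex source region
ISOCORTEX_INPUT_AXON_COUNTS: dict[str, int] = {
    "MOp": 159, "MOs": 393, "SSp": 488, "SSs": 97, "VISC": 8, "VIS": 83,
    "AUD": 26, "ECT": 4, "GU": 11, "ORB": 24, "ACA": 40, "RSP": 46,
    "FRP": 7, "PL": 8, "TEa": 10, "PTLp": 26, "AI": 42,
}


def total_used_morphologies() -> int:
    """Morphologies retained after all exclusions, summed over sources."""
    return sum(SOURCE_DATASET_SIZES.values()) - sum(
        EXCLUDED_BY_REPAIR.values()
    ) - sum(EXCLUDED_BY_PROJECTION_ANALYSIS.values())


def total_isocortex_input_axons() -> int:
    """Input axons for isocortex synthesis, summed over source regions."""
    return sum(ISOCORTEX_INPUT_AXON_COUNTS.values())
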
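"""Behaviour label vocabulary for the benthic-shark ethogram.

Raw video-coded labels distinguish swimming in the water column from
swimming on the floor; the modelling ethogram merges them into a single
``swim`` class when the two are statistically indistinguishable (see
:mod:`finbeat.ethogram`).  ``other`` collects rare heterogeneous
behaviours and ``out_of_camera`` marks unvalidated spans; neither is ever
modelled.
"""

#: Labels a video coder can assign to an event.
RAW_LABELS = ("rest", "swim_column", "swim_floor", "vertical_swim", "chew")

#: Labels excluded from feature tables and modelling.
EXCLUDED_LABELS = ("other", "out_of_camera")

#: Label used when the two swim classes are merged.
MERGED_SWIM = "swim"

#: The four-class modelling ethogram (alphabetical, the order used for
#: confusion matrices).
MODEL_LABELS = ("chew", "rest", "swim", "vertical_swim")

ALL_LABELS = RAW_LABELS + (MERGED_SWIM,) + EXCLUDED_LABELS
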
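"""Shipped pre-calibration constants for the 9-mer fallback mode.

Regenerated by ``scripts/derive_calibration.py`` (or ``prodege
calibrate``), which runs the synthetic calibration suite and rewrites
this file.  Do not edit by hand.  The full derivation grid is in
``docs/calibration_grid.tsv``.
"""

# Radius multiplier applied to the bin-linking distance ε in 9-mer mode:
# the largest factor whose median base-weighted specificity across the
# synthetic calibration grid stays at or above the target below.
PRECALIBRATED_FACTOR: float = 2.0

# Specificity the calibration aims for, and the seed the shipped factor
# was derived with.
CALIBRATION_TARGET_SPECIFICITY: float = 0.8
CALIBRATION_SEED: int = 20150609
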
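"""Reference summary statistics of the simultaneous scalp/intracranial
chewing dataset that this package models.

These printed summary values (five implanted patients S1-S5, three healthy
participants, six food conditions) are the empirical anchors of the
calibration and scaling procedure: no raw clinical recordings are public, so
the per-patient medians, trial counts and per-condition scalp amplitudes act
as inputs to the pipeline and as fixed points for its bookkeeping.
"""

from __future__ import annotations

import numpy as np

#: Chewing trials acquired per implanted patient.
TRIAL_COUNTS = {"S1": 551, "S2": 438, "S3": 252, "S4": 264, "S5": 147}

#: Printed total trial count across the five patients.
TRIAL_TOTAL = 1652

#: Per-patient median scalp (EEG) chewing-burst amplitude, microvolt.
EEG_MEDIAN_AMPLITUDES_UV = {
    "S1": 24.9, "S2": 25.1, "S3": 33.7, "S4": 38.8, "S5": 29.4,
}

#: Per-patient median intracranial (ECoG) chewing-burst amplitude, microvolt.
ECOG_MEDIAN_AMPLITUDES_UV = {
    "S1": 5.0, "S2": 5.4, "S3": 6.4, "S4": 4.3, "S5": 7.6,
}

#: Mean scalp chewing amplitude per food condition in healthy participants,
#: microvolt.  Used as the noninvasive scaling table.
CONDITION_AMPLITUDES_UV = {
    "yoghurt": 46.6,
    "banana": 45.7,
    "carrot": 116.4,
    "gum": 107.3,
    "candy": 139.9,
    "licorice": 155.2,
}

#: Intracranial contacts with a significant chewing-related spectral power
#: increase, out of all analyzed contacts.
SIGNIFICANT_CONTACTS = (406, 410)

#: Range of median chewing repetition rates across patients/participants, Hz.
CHEW_RATE_RANGE_HZ = (0.82, 1.8)

#: Mean scalp-to-intracranial attenuation factor of chewing-burst amplitude.
MEAN_ATTENUATION = 5.5

#: Cortical electric-field strength reported to modulate ongoing neural
#: activity, V/m.  The dosimetry threshold of the whole pipeline.
EF_THRESHOLD_V_PER_M = 0.2


def significant_contact_percentage() -> float:
    """Percentage of analyzed contacts with a significant chewing response."""
    k, n = SIGNIFICANT_CONTACTS
    return 100.0 * k / n


def trial_count_total() -> int:
    """Sum of the per-patient trial counts (bookkeeping check)."""
    return int(np.sum(list(TRIAL_COUNTS.values())))
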
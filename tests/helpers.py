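"""Small shared builders for the test suite."""

import numpy as np

from perifield.io import ExamRecord


def make_exam(rf_counts=(1, 1, 20), subject="s001", eye="OD", test=1, values=None):
    fp, fn, catch = rf_counts
    if values is None:
        values = np.linspace(0, 20, 185)
    return ExamRecord(
        subject_id=subject, eye=eye, test_index=test, day_index=1,
        sensitivities=values, false_positives=fp, false_negatives=fn,
        catch_trials=catch,
    )
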
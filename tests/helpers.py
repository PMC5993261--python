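"""Shared helpers for validating inference against simulator ground truth."""
import numpy as np
from scipy.optimize import linear_sum_assignment

from dfcstates.preprocess import TimeCoursePreprocessor
from dfcstates.windows import WindowParams, dfc_stack


def majority_window_labels(volume_labels, window_length=15, step=1):
    """Ground-truth label per window = majority vote over its volumes."""
    volume_labels = np.asarray(volume_labels)
    n = len(volume_labels) - window_length + 1
    out = np.empty(n, dtype=int)
    for s in range(0, n, step):
        w = volume_labels[s:s + window_length]
        vals, cnt = np.unique(w, return_counts=True)
        out[s] = vals[cnt.argmax()]
    return out


def cohort_features(cohort, window_length=15, n_discard=0, lowpass=False):
    """Pooled (windows x edges) features plus per-run keys, lengths and
    ground-truth majority window labels."""
    prep = TimeCoursePreprocessor(n_discard=n_discard, apply_lowpass=lowpass)
    keys, lengths, feats, truth = [], [], [], []
    params = WindowParams(window_length=window_length)
    for rec in cohort:
        for ts, seq in zip(rec.runs, rec.state_sequences):
            pts = prep.prepare_timeseries(ts)
            F = dfc_stack(pts, params).to_features()
            keys.append((rec.subject_id, ts.run_id))
            lengths.append(F.shape[0])
            feats.append(F)
            truth.append(majority_window_labels(seq[n_discard:],
                                                window_length))
    return np.vstack(feats), keys, lengths, truth


def align_states(true_labels, est_labels, k):
    """Map estimated 1-based state ids onto ground-truth ids (Hungarian
    matching on the confusion matrix)."""
    conf = np.zeros((k, k))
    for t, e in zip(true_labels, est_labels):
        conf[t - 1, e - 1] += 1
    row, col = linear_sum_assignment(-conf)
    return {c + 1: r + 1 for r, c in zip(row, col)}
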
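import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def merge_truth_runs(ground_truth, gap_max=3e-3, min_duration=4e-3, step_max=90.0):
    """Apply the run-assembly convention to simulator ground truth.

    Attachments shorter than ``min_duration`` are below the detector's
    minimum event duration; consecutive attachments separated by less
    than ``gap_max`` in the same force phase (position jump below
    ``step_max``) are one run by the assembly rule, mirroring what the
    detector chain reports.
    """
    kept = [g for g in ground_truth if g["t_detach"] - g["t_attach"] > min_duration]
    out = []
    for g in kept:
        g = dict(g, merged=False)
        prev = out[-1] if out else None
        if (prev is not None
                and g["t_attach"] - prev["t_detach"] < gap_max
                and np.sign(g["force"]) == np.sign(prev["force"])
                and abs(g["pos_attach"] - prev["pos_detach"]) < step_max):
            prev["t_detach"] = g["t_detach"]
            prev["pos_detach"] = g["pos_detach"]
            prev["steps"] = prev["steps"] + g["steps"]
            prev["truncated"] = g["truncated"]
            prev["merged"] = True
        else:
            out.append(g)
    return out


def is_resolvable(truth_run, window_s=1e-3):
    """True when every inter-event gap exceeds the detector resolution.

    For such runs (untruncated, unmerged, all dwells > 2.5 windows) the
    detector chain must reproduce the ground truth exactly.
    """
    times = ([truth_run["t_attach"]]
             + [t for t, _ in truth_run["steps"]]
             + [truth_run["t_detach"]])
    gaps = np.diff(times)
    return (not truth_run["truncated"] and not truth_run["merged"]
            and (gaps.size == 0 or gaps.min() > 2.5 * window_s))
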
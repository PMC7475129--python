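import numpy as np
import pytest

import cihpheno as cp


@pytest.fixture(scope="session")
def clean_trace():
    """Noiseless 2 min resting trace at the default rat protocol."""
    spec = cp.SimProtocol(duration_s=120.0, noise_sd=0.0, seed=11)
    trace, log = cp.simulate_flow_trace(spec)
    return spec, trace, log


@pytest.fixture(scope="session")
def eventful_trace():
    """10 min trace with planted sighs, apnoeas (one post-sigh) and artifacts."""
    spec = cp.SimProtocol(
        duration_s=600.0,
        noise_sd=0.02,
        sigh_times_s=(60.0, 200.0, 420.0),
        sigh_gain=2.5,
        apnoea_specs=(
            cp.ApnoeaSpec(120.0, 2.5),
            cp.ApnoeaSpec(300.0, 2.5, post_sigh=True),
            cp.ApnoeaSpec(480.0, 2.8),
        ),
        artifact_specs=((520.0, 3.0), (560.0, 2.0)),
        seed=7,
    )
    trace, log = cp.simulate_flow_trace(spec)
    return spec, trace, log


def score_trace(trace, min_vt_ml=0.2, artifact_windows=()):
    """Standard scoring chain used across tests: segment -> reject -> detect."""
    breaths = cp.segment_breaths(trace, min_vt_ml=min_vt_ml)
    breaths = cp.reject_artifacts(breaths, cp.ArtifactRules(windows=tuple(artifact_windows)))
    sighs = cp.detect_sighs(breaths, body_mass_g=trace.body_mass_g or 300.0)
    apnoeas = cp.detect_apnoeas(breaths, sighs=sighs)
    classified = cp.classify_apnoeas(apnoeas, sighs, breaths)
    return breaths, sighs, classified


def match_events(planted, detected, tol_s=1.0):
    """Greedy onset matching; returns (tp, fp, fn)."""
    used = set()
    tp = 0
    for p in planted:
        for i, d in enumerate(detected):
            if i not in used and abs(p.onset_s - d.onset_s) < tol_s:
                used.add(i)
                tp += 1
                break
    return tp, len(detected) - tp, len(planted) - tp
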
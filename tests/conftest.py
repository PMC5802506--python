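import numpy as np
import pandas as pd
import pytest

from mirelapse.matrix import LOG2, ExpressionMatrix, PairingTable
from mirelapse.profiling import normalize_counts
from mirelapse.synthetic import (
    generate_mrna_expression,
    generate_paired_mirna_counts,
    generate_target_resources,
)


def make_log2_matrix(values, sample_ids=None, patients=None, phases=None, features=None):
    """Small log2-scale ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = features or [f"f{i}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samp)]
    patients = patients or sample_ids
    phases = phases or ["primary"] * n_samp
    meta = pd.DataFrame(
        {"patient": patients, "phase": phases}, index=pd.Index(sample_ids, name="sample")
    )
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=sample_ids), meta, LOG2)


def make_paired_log2(diffs, base=8.0):
    """Paired matrix where relapse - primary equals the given per-patient diffs.

    ``diffs``: array (n_features, n_pairs).
    """
    diffs = np.asarray(diffs, dtype=float)
    n_feat, n_pairs = diffs.shape
    patients = [f"P{i}" for i in range(n_pairs)]
    cols, ids, phases, pats = [], [], [], []
    for j, p in enumerate(patients):
        cols.append(np.full(n_feat, base))
        ids.append(f"{p}_pri")
        phases.append("primary")
        pats.append(p)
        cols.append(base + diffs[:, j])
        ids.append(f"{p}_rel")
        phases.append("relapse")
        pats.append(p)
    expr = make_log2_matrix(np.column_stack(cols), ids, pats, phases)
    pairing = PairingTable(
        pd.DataFrame(
            {
                "patient": patients,
                "primary_sample": [f"{p}_pri" for p in patients],
                "relapse_sample": [f"{p}_rel" for p in patients],
            }
        )
    )
    return expr, pairing


@pytest.fixture(scope="session")
def paired_dataset():
    """Mid-size synthetic discovery dataset with ground truth."""
    counts, truth, pairing = generate_paired_mirna_counts(
        n_mirnas=150, n_pairs=7, de_fraction=13 / 150, effect_log2fc=2.0,
        dispersion=0.1, depth=2e5, seed=101,
    )
    log2 = normalize_counts(counts)
    mrna = generate_mrna_expression(
        counts, truth, noise_sd=0.2, n_genes=400, targets_per_mirna=20,
        strength=-1.5, seed=102,
    )
    resources = generate_target_resources(truth, sensitivity=0.8, fp_rate=0.0005, seed=103)
    return {
        "counts": counts,
        "log2": log2,
        "mrna": mrna,
        "truth": truth,
        "pairing": pairing,
        "resources": resources,
    }
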
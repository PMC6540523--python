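"""Shared fixtures: a hand-derived curation toy table and small trained
models reused across test modules (session-scoped to keep the suite fast)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mhcbind as m

# ---------------------------------------------------------------------------
# Toy raw binding table exercising every curation rule. The expected cleaned
# output below is derived by hand from the documented rules:
#   blacklist -> filters (allele, length, ambiguity) -> label policy
#   -> de-duplication -> majority vote -> tie exclusion.
# ---------------------------------------------------------------------------
TOY_ROWS = [
    # plain keeps (including one needing whitespace/case normalization)
    ("HLA-A*01:01", "SIINFEKLM", "Positive-High", "s1"),
    ("HLA-B*07:02", "AAAWWWKKM", "Positive", "s1"),
    ("HLA-C*07:01", "LLLLLLLL", "Negative", "s1"),
    (" hla-a*02:01 ", "KLMNPQRST", "Positive", "s1"),
    ("HLA-A*02:01", "GILGFVFTL", "Positive-High", "s2"),
    ("HLA-A*02:01", "NLVPMVATV", "Positive", "s2"),
    ("HLA-B*07:02", "TPRVTGGGAM", "Positive", "s2"),
    ("HLA-B*07:02", "RPHERNGFTVL", "Negative", "s2"),
    ("HLA-C*07:02", "VRFPNITNL", "Positive-High", "s2"),
    ("HLA-A*01:01", "CTELKLSDY", "Negative", "s2"),
    ("HLA-A*03:01", "KVFPCALINK", "Positive", "s3"),
    ("HLA-B*35:01", "IPSINVHHY", "Positive", "s3"),
    ("HLA-C*04:01", "QYDDAVYLL", "Negative", "s3"),
    ("HLA-A*01:01", "ATDSLNNEY", "Positive", "s3"),
    # length violations (7-mer, 16-mer)
    ("HLA-A*01:01", "SHORTPE", "Positive", "s1"),
    ("HLA-A*01:01", "AAAAAAAAAAAAAAAA", "Positive", "s1"),
    # ambiguous letters B, X, J, Z
    ("HLA-A*01:01", "SIBNFEKLM", "Positive", "s1"),
    ("HLA-A*01:01", "SIXNFEKLM", "Positive", "s1"),
    ("HLA-A*01:01", "SIJNFEKLM", "Positive", "s1"),
    ("HLA-A*01:01", "SIZNFEKLM", "Positive", "s1"),
    # nonspecific allele names
    ("HLA-A30", "ACDEFGHIK", "Positive", "s1"),
    ("MHC class I", "ACDEFGHIK", "Positive", "s1"),
    # low-confidence labels dropped under the strict policy
    ("HLA-A*01:01", "DDDDDDDD", "Positive-Intermediate", "s1"),
    ("HLA-A*01:01", "EEEEEEEE", "Positive-Low", "s1"),
    # blacklist: positive record from sBAD removed before voting,
    # so the negative from s1 survives
    ("HLA-B*27:05", "RRYQKSTEL", "Positive", "sBAD"),
    ("HLA-B*27:05", "RRYQKSTEL", "Negative", "s1"),
    # majority vote: 3 positives + 1 negative -> one positive record
    ("HLA-A*02:01", "YLLPAIVHI", "Positive", "s1"),
    ("HLA-A*02:01", "YLLPAIVHI", "Positive", "s2"),
    ("HLA-A*02:01", "YLLPAIVHI", "Positive-High", "s3"),
    ("HLA-A*02:01", "YLLPAIVHI", "Negative", "s4"),
    # exact tie: 2 positives + 2 negatives -> pair excluded entirely
    ("HLA-B*07:02", "APRGPHGGA", "Positive", "s1"),
    ("HLA-B*07:02", "APRGPHGGA", "Positive", "s2"),
    ("HLA-B*07:02", "APRGPHGGA", "Negative", "s3"),
    ("HLA-B*07:02", "APRGPHGGA", "Negative", "s4"),
    # five identical duplicates -> one record
    ("HLA-C*04:01", "FFFFFFFF", "Positive", "s1"),
    ("HLA-C*04:01", "FFFFFFFF", "Positive", "s2"),
    ("HLA-C*04:01", "FFFFFFFF", "Positive", "s3"),
    ("HLA-C*04:01", "FFFFFFFF", "Positive", "s4"),
    ("HLA-C*04:01", "FFFFFFFF", "Positive", "s5"),
    # unparseable label -> parse-time reject, never reaches curation
    ("HLA-A*01:01", "ACDEFGHIK", "Garbage", "s1"),
]

TOY_BLACKLIST = {"sBAD"}

#: hand-derived cleaned output (allele, peptide, binary label)
TOY_EXPECTED = {
    ("HLA-A*01:01", "SIINFEKLM", 1),
    ("HLA-B*07:02", "AAAWWWKKM", 1),
    ("HLA-C*07:01", "LLLLLLLL", 0),
    ("HLA-A*02:01", "KLMNPQRST", 1),
    ("HLA-A*02:01", "GILGFVFTL", 1),
    ("HLA-A*02:01", "NLVPMVATV", 1),
    ("HLA-B*07:02", "TPRVTGGGAM", 1),
    ("HLA-B*07:02", "RPHERNGFTVL", 0),
    ("HLA-C*07:02", "VRFPNITNL", 1),
    ("HLA-A*01:01", "CTELKLSDY", 0),
    ("HLA-A*03:01", "KVFPCALINK", 1),
    ("HLA-B*35:01", "IPSINVHHY", 1),
    ("HLA-C*04:01", "QYDDAVYLL", 0),
    ("HLA-A*01:01", "ATDSLNNEY", 1),
    ("HLA-B*27:05", "RRYQKSTEL", 0),
    ("HLA-A*02:01", "YLLPAIVHI", 1),
    ("HLA-C*04:01", "FFFFFFFF", 1),
}

#: hand-derived per-rule drop counts for the strict policy + blacklist
TOY_EXPECTED_AUDIT = {
    "filter:length": 2,
    "filter:ambiguous_aa": 4,
    "filter:nonspecific_allele": 2,
    "label_policy_dropped": 2,
    "blacklisted_source": 1,
    "duplicate_collapsed": 4,
    "conflict_majority_collapsed": 3,
    "conflict_tie_excluded": 4,
}


@pytest.fixture()
def toy_table_path(tmp_path):
    path = tmp_path / "raw.tsv"
    pd.DataFrame(TOY_ROWS, columns=["allele", "peptide", "label", "source"]
                 ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture(scope="session")
def synthetic_study():
    """Small synthetic study shared by model-level tests."""
    spec = m.SyntheticAlleleSpec(n_alleles=6, seed=7)
    alleles, pseudo, rule = m.generate_alleles(spec)
    ds, flips = m.generate_binding_data(
        alleles, pseudo, rule,
        m.SyntheticDatasetSpec(n_records=900, noise=0.0, seed=7))
    return {"alleles": alleles, "pseudo": pseudo, "rule": rule,
            "dataset": ds, "flips": flips}


SMALL_PARAMS = dict(gru_units=16, mhc_fc_units=50, head_fc_units=64,
                    max_epochs=15, patience=4, learning_rate=3e-3)


@pytest.fixture(scope="session")
def trained_sequence_model(synthetic_study):
    df = synthetic_study["dataset"].to_frame()
    clf = m.BindingClassifier(pseudo_sequences=synthetic_study["pseudo"],
                              random_state=0, **SMALL_PARAMS)
    clf.fit(df[["peptide", "allele"]], df["label"].to_numpy())
    return clf


@pytest.fixture(scope="session")
def trained_onehot_model(synthetic_study):
    df = synthetic_study["dataset"].to_frame()
    clf = m.BindingClassifier(mhc_repr="one_hot_allele", random_state=0,
                              **SMALL_PARAMS)
    clf.fit(df[["peptide", "allele"]], df["label"].to_numpy())
    return clf
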
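"""Shared cohort loading for the analysis drivers."""

from pathlib import Path

from qheart.cohort import CohortSpec, encode_dataset, generate_cohort, read_cohort_csv


def load_default_data(seed: int):
    spec = CohortSpec()
    path = Path("results/cohort.csv")
    table = (read_cohort_csv(path) if path.exists()
             else generate_cohort(spec, seed=seed))
    return encode_dataset(table, spec, split_seed=seed)
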
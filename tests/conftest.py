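import numpy as np
import pandas as pd

from erdomains.io_tables import AbundanceMatrix, SampleMeta


def make_matrix(values, accessions=None, samples=None, genes=None):
    """Small AbundanceMatrix builder for unit tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if accessions is None:
        accessions = [f"P{i + 1}" for i in range(n)]
    if genes is None:
        genes = [a.lower() for a in accessions]
    if samples is None:
        samples = [
            SampleMeta(f"s{j + 1}", f"bait{j + 1}", "EGFP", "598", 1, False)
            for j in range(m)
        ]
    proteins = pd.DataFrame(
        {"accession": accessions, "gene": genes, "description": [""] * n}
    )
    return AbundanceMatrix(proteins=proteins, samples=samples, values=values)


def two_bait_samples(baits=("A", "B"), antibodies=("ab1", "ab2"), reps=(1,),
                     tag="EGFP", controls=False):
    samples = [
        SampleMeta(f"{b}.{ab}.r{r}", b, tag, ab, r, False)
        for b in baits for ab in antibodies for r in reps
    ]
    if controls:
        samples += [
            SampleMeta(f"ctrl.{ab}.r{r}", "tag-only", tag, ab, r, True)
            for ab in antibodies for r in reps
        ]
    return samples
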
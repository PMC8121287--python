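"""Associate signature exposures with sample covariates.

Continuous covariates are tested by Pearson correlation, binary ones by a
two-sided Mann-Whitney U test (effect = difference of group means); all
p-values of the call are Benjamini-Hochberg adjusted. Rows with FDR < 0.05
would be the reportable associations.
"""

import numpy as np
import pandas as pd

import cnsig

rng = np.random.default_rng(3)
n = 40
samples = [f"S{i}" for i in range(n)]

exposures = pd.DataFrame(
    {"Sig1": rng.uniform(0, 1, n), "Sig2": rng.uniform(0, 1, n)}, index=samples
)
covariates = pd.DataFrame(
    {
        # ploidy tracks Sig1 by construction; mutation status is noise
        "ploidy": 2 + 2 * exposures["Sig1"] + rng.normal(0, 0.2, n),
        "driver_mutated": rng.integers(0, 2, n),
    },
    index=samples,
)

table = cnsig.associate_exposures(
    exposures, covariates,
    kinds={"ploidy": "continuous", "driver_mutated": "binary"},
)
print(table.round(4).to_string(index=False))
print("\nFDR < 0.05:", table.loc[table["fdr"] < 0.05, ["signature", "covariate"]]
      .to_records(index=False).tolist())
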
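"""Shared configuration for the numbered analysis drivers.

The demonstration study is a synthetic 40-cell-line cohort with multi-probe
genes, including long genes (> 2 probesets or > 20 probes).  Because each
probeset responds to a gene's across-probe mean methylation, single-probe
regressions attenuate the coefficient by (rho + (1 - rho)/n); the study
therefore uses a moderate inter-probe correlation (rho = 0.3, the upper end
of what two-color arrays show between neighboring probes) and an effect
magnitude of 2 so that truly associated genes still clear the
|coefficient| > 0.5 filter at realistic probe counts.
"""

from pathlib import Path

from methexpr import SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"
DATA = OUT / "data"

SEED = 2026

STUDY = SyntheticConfig(
    n_samples=40,
    n_genes=80,
    m_range=(1, 3),
    n_range=(2, 30),
    frac_positive=0.3,
    frac_negative=0.3,
    beta1_magnitude=2.0,
    beta2=1.0,
    sigma=1.0,
    meth_mu_range=(-2.0, 2.0),
    meth_sd=1.2,
    rho=0.3,
    seed=SEED,
)
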
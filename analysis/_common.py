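"""Shared configuration for the numbered analysis drivers.

One synthetic two-condition study (sham vs irradiated) with both 5mC and
5hmC assays, two pools per condition: 10 Mb genome, 2000 genes, 200
planted enrichment domains per assay of which 100 shift by a fold ratio
of 3 between conditions, 300 DE genes of which 100 are coupled to an
intragenic 5hmC gain.
"""

from pathlib import Path

from dipseq import PipelineConfig, SimParams

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA_DIR = RESULTS / "data"
SEED = 1

ASSAYS = ("5mC", "5hmC")

CONFIG = PipelineConfig(
    window_bp=500,          # resolves the 1-kb planted domains
    n_permutations=300,
    enrich_alpha=1e-5,      # genome-wide-corrected domain threshold
    rng_seed=SEED,
)

SIM_PARAMS = SimParams(
    n_genes=2000,
    n_domains=200,
    n_dmrs=100,
    n_de_genes=300,
    n_coupled_genes=100,
    n_pools=2,
    rng_seed=SEED,
)
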
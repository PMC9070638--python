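"""End-to-end run: simulate an input bundle to disk, then execute the
whole pipeline from files, exactly as the CLI `ncpmap run` would."""

import json
import tempfile
from pathlib import Path

from ncpmap import RunConfig, SimulationSpec, run_pipeline, simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    out = Path(tmp) / "results"
    paths = simulate_dataset(SimulationSpec(seed=11)).write(str(bundle))
    config = RunConfig(
        genome=paths["genome"],
        annotation=paths["annotation"],
        identifications=paths["identifications"],
        snps=paths["snps"],
        tracks={"qtl": paths["qtl"], "ltr": paths["ltr"], "sweep": paths["sweep"]},
        outdir=str(out),
        min_len=5,
        seed=11,
    )
    manifest = run_pipeline(config)
    print("stage counts:", json.dumps(manifest["counts"], indent=2, default=str))
    print("enrichment:", json.dumps(manifest["enrichment"], indent=2))
    print("outputs written:", sorted(p.name for p in out.iterdir()))
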
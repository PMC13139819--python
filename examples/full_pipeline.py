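"""One-command reproduction: synthetic study in, full report out.

Writes a complete synthetic study (band calls, alignment + epitopes, plate,
inhibition series, quant.sf tree) to a temporary directory, then runs all
four analysis stages from a single configuration.
"""

import json
import tempfile
from pathlib import Path

from allerprofile import RunConfig, run_pipeline
from allerprofile.synthetic import SimulationConfig, generate_all

with tempfile.TemporaryDirectory() as tmp:
    study = Path(tmp) / "study"
    generate_all(study, SimulationConfig(seed=7))

    config = RunConfig(
        out_dir=str(Path(tmp) / "out"),
        band_calls=str(study / "band_calls.tsv"),
        alignment=str(study / "alignment.fasta"),
        epitopes=str(study / "epitopes.tsv"),
        plate=str(study / "plate.tsv"),
        inhibition=str(study / "inhibition.tsv"),
        quant_dir=str(study / "quant"),
        mapping=str(study / "mapping.tsv"),
        samples=str(study / "samples.tsv"),
    )
    report = run_pipeline(config)

    print("stages run:", ", ".join(report["stages"]))
    print("dendrogram:", report["stages"]["bands"]["newick"])
    sero = report["stages"]["serology"]
    print(f"sensitization: {sero['n_positive']}/{sero['n_tested']} "
          f"= {sero['sensitization_rate']}%")
    strongest = max(sero["inhibition"], key=lambda s: s["max_inhibition"])
    print(f"strongest inhibitor: {strongest['inhibitor']} "
          f"at {strongest['max_inhibition']}%")
    print("protein similarity:",
          json.dumps(report["stages"]["conservation"]["protein_similarity"]))
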
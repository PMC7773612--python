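#!/usr/bin/env python
"""Generate the study-design phantom dataset and write it to results/phantom/.

Emulates the measurement campaign the pipeline was built for: 115 training
locations measured in triplicate plus one gridded test specimen (9x14 cells,
55 measurable) with spatially smooth water / uronic-acid / hydroxyproline
fields, band-structured NIR spectra, multiplicative/additive scatter and
channel noise.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from nirmap.io_formats import write_references, write_spectra
from nirmap.synthetic import PhantomSpec, generate_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/phantom"))
    args = ap.parse_args()

    spec = PhantomSpec()
    ds = generate_dataset(spec, seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    write_spectra(ds.train_spectra, args.out / "train_spectra.csv")
    write_references(ds.train_references, args.out / "train_references.csv")
    write_spectra(ds.test_spectra, args.out / "test_spectra.csv")
    write_references(ds.test_references, args.out / "test_references.csv")
    (args.out / "phantom_spec.json").write_text(
        json.dumps({"seed": args.seed, **spec.to_dict()}, indent=2)
    )

    print(f"phantom written to {args.out}")
    print(f"  training: {ds.train_spectra.n_samples} spectra "
          f"({len(set(ds.train_spectra.groups))} locations x {spec.replicates} replicates)")
    print(f"  test grid: {ds.test_mask.shape[0]}x{ds.test_mask.shape[1]} cells, "
          f"{int(ds.test_mask.sum())} measured / {int((~ds.test_mask).sum())} unmeasured")
    print(f"  axis: {ds.train_spectra.n_channels} channels, "
          f"{ds.train_spectra.axis.wavelengths[0]:.0f}-"
          f"{ds.train_spectra.axis.wavelengths[-1]:.0f} nm")


if __name__ == "__main__":
    main()
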
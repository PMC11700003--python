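#!/usr/bin/env python
"""Regenerate the per-element coefficient CSV fixtures shipped with ccbrachy."""
from pathlib import Path

from ccbrachy.xs_build import write_element_csvs

if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "ccbrachy" / "data" / "elements"
    write_element_csvs(out)
    print(f"wrote element tables to {out}")
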
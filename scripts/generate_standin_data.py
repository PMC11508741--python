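"""Regenerate the packaged stand-in mechanism and ranges data files.

The canonical definition is :func:`basalcal.synthetic.build_standin_model`;
this script serializes it into ``src/basalcal/data/`` so the packaged files
and the builder never drift (a test asserts they agree).
"""

from pathlib import Path

from basalcal.mechanism import write_mechanism
from basalcal.ranges import write_ranges_csv
from basalcal.synthetic import build_standin_model


def main() -> None:
    data = Path(__file__).resolve().parent.parent / "src" / "basalcal" / "data"
    data.mkdir(parents=True, exist_ok=True)
    mech, ranges = build_standin_model()
    write_mechanism(mech, data / "standin_mechanism.yaml")
    write_ranges_csv(ranges, data / "standin_ranges.csv")
    print(f"wrote {data}/standin_mechanism.yaml ({mech.n_reactions} reactions, "
          f"{mech.n_species} species) and standin_ranges.csv ({len(ranges)} ranges)")


if __name__ == "__main__":
    main()
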
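#!/bin/sh
# Shell workflow: simulate a landscape, then assess it from files.
# Same seed + config always reproduce byte-identical layers and tables.
set -e

workdir=$(mktemp -d)

cat > "$workdir/sim.yaml" <<EOF
n_states: 2
state_size: 800.0
coverage: 0.3
n_parcels: 2000
EOF

prioralign simulate --config "$workdir/sim.yaml" --seed 11 --out-dir "$workdir/landscape"

prioralign assess \
  --lands "$workdir/landscape/lands.geojson" \
  --priorities "$workdir/landscape/priorities.geojson" \
  --states "$workdir/landscape/states.geojson" \
  --out-dir "$workdir/report"

echo
echo "by_period.csv:"
cat "$workdir/report/by_period.csv"
echo
echo "centroid_test.json:"
cat "$workdir/report/centroid_test.json"
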
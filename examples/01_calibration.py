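"""Fit the bundled voltage/angle calibration and convert both ways.

The table holds bench measurements of each sensor channel's output voltage
(mV) at known bend/tilt angles from -60 to +60 degrees.  The piecewise-linear
interpolant is exact at every node; the affine fit summarises the nearly
linear response.
"""

from fhposture import (
    angle_to_voltage,
    bundled_table_path,
    fit_channel_calibration,
    load_calibration_table,
    voltage_to_angle,
)

table = load_calibration_table(bundled_table_path())
print(f"calibration nodes: {table.degrees[0]:.0f}..{table.degrees[-1]:.0f} deg, "
      f"{table.degrees.size} per channel, channels {table.channel_names}")

for name in table.channel_names:
    cal = fit_channel_calibration(table, name)
    print(f"  {name:>4}: slope {cal.slope:6.2f} mV/deg, intercept "
          f"{cal.intercept:7.1f} mV, affine residual RMS {cal.residual_rms:5.1f} mV")

flex = fit_channel_calibration(table, "flex")
print(f"flex voltage at 30 deg bend : {angle_to_voltage(flex, 30.0):.0f} mV")
print(f"flex angle at 1811 mV       : {voltage_to_angle(flex, 1811.0):.1f} deg")
print("(a small residual RMS means the affine summary is close to the exact "
      "node map, i.e. the sensor responds nearly linearly)")
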
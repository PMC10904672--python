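# Desk-scale placeholder scanner.
#
# Clinical geometries are vendor-confidential; these values are documented
# placeholders chosen to be typical of a third-generation axial CT while
# keeping simulations tractable on a workstation.  A full-resolution profile
# (896 channels x 320 rows, 1200 views) can be written by editing this file;
# every pipeline stage reads geometry exclusively from here.
geometry:
  source_to_isocenter_mm: 600.0
  source_to_detector_mm: 1100.0
  n_channels: 288
  n_rows: 16
  channel_angular_pitch_rad: 0.0012
  row_pitch_mm: 1.0
  views_per_rotation: 360
  rotation_time_s: 0.5
  collimation_mm: 8.7   # n_rows * row_pitch / magnification at isocenter
focal_spots:
  large: {width_mm: 1.4, length_mm: 1.4, label: large}
  small: {width_mm: 0.7, length_mm: 0.7, label: small}
protocols:
  body_120: {tube_voltage_kv: 120.0, tube_current_ma: 200.0,
             exposure_time_s: 0.5, bowtie_id: body, focal_spot_label: large}
  body_100: {tube_voltage_kv: 100.0, tube_current_ma: 200.0,
             exposure_time_s: 0.5, bowtie_id: body, focal_spot_label: large}
  head_120: {tube_voltage_kv: 120.0, tube_current_ma: 140.0,
             exposure_time_s: 0.5, bowtie_id: body, focal_spot_label: small}
subsampling: {L: 3, K: 3, M: 4}
allowed_voltages_kv: [80.0, 100.0, 120.0, 135.0]
bowtie_ids: [body]
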
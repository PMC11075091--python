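{
  "geometry": {
    "d_source_samplemask": "69 cm",
    "d_samplemask_sample": "3 cm",
    "d_source_detmask": "84 cm",
    "d_source_detector": "86 cm",
    "effective_energy_kev": 18.0,
    "m_s_override": null
  },
  "source": {
    "fwhm_horizontal": "70 um"
  },
  "sample_mask": {
    "bands": [
      {"name": "20um_slits", "shape": "slit", "aperture": "20 um", "period": "79 um", "band_height": "1 cm", "septa_transmission": 0.0},
      {"name": "10um_slits", "shape": "slit", "aperture": "10 um", "period": "79 um", "band_height": "1 cm", "septa_transmission": 0.0},
      {"name": "5um_slits", "shape": "slit", "aperture": "5 um", "period": "79 um", "band_height": "1 cm", "septa_transmission": 0.0},
      {"name": "10um_circles", "shape": "circle", "aperture": "10 um", "period": "79 um", "band_height": "1 cm", "septa_transmission": 0.0}
    ]
  },
  "detector": {
    "pixel_pitch": "50 um",
    "n_cols": 2400,
    "n_rows": 2400,
    "detmask_aperture": "17 um",
    "detmask_period": "98 um",
    "line_skipping": true
  },
  "acquisition": {
    "working_point_fraction": 0.5,
    "flank": "positive",
    "effective_pixel_height": "40 um"
  }
}
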
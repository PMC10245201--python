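# Minimal synthetic study: 2 species x 2 localities.
seed: 7
sympatry:
  Tarapoto: [varia, imita]
  Chazuta: [varia, imita]
input:
  study:
    populations:
      - species: varia
        locality: Tarapoto
        n_individuals: 8
        colors:
          head:  {hue_mean: 50.0,  hue_sd: 6.0, sat_mean: 0.85, sat_sd: 0.04}
          back:  {hue_mean: 55.0,  hue_sd: 6.0, sat_mean: 0.80, sat_sd: 0.04}
          limb:  {hue_mean: 200.0, hue_sd: 6.0, sat_mean: 0.70, sat_sd: 0.04}
        dorsal_band_count_mean: 3.0
        dorsal_band_count_sd: 0.6
        limb_band_count_mean: 2.0
        limb_band_count_sd: 0.4
        pattern_class: striped
        convergence: 0.6
      - species: imita
        locality: Tarapoto
        n_individuals: 8
        colors:
          head:  {hue_mean: 90.0,  hue_sd: 6.0, sat_mean: 0.85, sat_sd: 0.04}
          back:  {hue_mean: 95.0,  hue_sd: 6.0, sat_mean: 0.80, sat_sd: 0.04}
          limb:  {hue_mean: 230.0, hue_sd: 6.0, sat_mean: 0.70, sat_sd: 0.04}
        dorsal_band_count_mean: 4.0
        dorsal_band_count_sd: 0.6
        limb_band_count_mean: 2.0
        limb_band_count_sd: 0.4
        pattern_class: striped
        convergence: 0.6
      - species: varia
        locality: Chazuta
        n_individuals: 8
        colors:
          head:  {hue_mean: 140.0, hue_sd: 10.0, sat_mean: 0.85, sat_sd: 0.05}
          back:  {hue_mean: 150.0, hue_sd: 10.0, sat_mean: 0.80, sat_sd: 0.05}
          limb:  {hue_mean: 300.0, hue_sd: 10.0, sat_mean: 0.70, sat_sd: 0.05}
        dorsal_band_count_mean: 2.0
        dorsal_band_count_sd: 0.9
        limb_band_count_mean: 1.0
        limb_band_count_sd: 0.5
        pattern_class: spotted
        convergence: 0.1
      - species: imita
        locality: Chazuta
        n_individuals: 8
        colors:
          head:  {hue_mean: 270.0, hue_sd: 10.0, sat_mean: 0.85, sat_sd: 0.05}
          back:  {hue_mean: 280.0, hue_sd: 10.0, sat_mean: 0.80, sat_sd: 0.05}
          limb:  {hue_mean: 20.0,  hue_sd: 10.0, sat_mean: 0.70, sat_sd: 0.05}
        dorsal_band_count_mean: 3.0
        dorsal_band_count_sd: 0.9
        limb_band_count_mean: 1.0
        limb_band_count_sd: 0.5
        pattern_class: spotted
        convergence: 0.1
options:
  grid_size: 32
  hue_mode: circular
  back_mode: pair
  ms_aggregate: sum
  render_images: false
  plots: true
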
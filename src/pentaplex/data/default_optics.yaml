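leds:
  L385:
    emission: spectra/led_L385_emission.csv
    filter: spectra/led_L385_filter.csv
  L470:
    emission: spectra/led_L470_emission.csv
    filter: spectra/led_L470_filter.csv
  L567:
    emission: spectra/led_L567_emission.csv
    filter: spectra/led_L567_filter.csv
  L627:
    emission: spectra/led_L627_emission.csv
    filter: spectra/led_L627_filter.csv
  L720:
    emission: spectra/led_L720_emission.csv
    filter: spectra/led_L720_filter.csv
fluorochromes:
  DAPI:
    excitation: spectra/fluor_DAPI_excitation.csv
    emission: spectra/fluor_DAPI_emission.csv
    brightness: 1.0
    window: 0
  BV605:
    excitation: spectra/fluor_BV605_excitation.csv
    emission: spectra/fluor_BV605_emission.csv
    brightness: 0.8
    window: 2
  AF488:
    excitation: spectra/fluor_AF488_excitation.csv
    emission: spectra/fluor_AF488_emission.csv
    brightness: 1.0
    window: 1
  AF555:
    excitation: spectra/fluor_AF555_excitation.csv
    emission: spectra/fluor_AF555_emission.csv
    brightness: 0.9
    window: 2
  AF647:
    excitation: spectra/fluor_AF647_excitation.csv
    emission: spectra/fluor_AF647_emission.csv
    brightness: 1.0
    window: 3
  CF750:
    excitation: spectra/fluor_CF750_excitation.csv
    emission: spectra/fluor_CF750_emission.csv
    brightness: 0.5
    window: 4
penta:
  transmission: spectra/penta_transmission.csv
  passbands:
  - - 414
    - 450
  - - 501
    - 529
  - - 580
    - 610
  - - 661
    - 701
  - - 769
    - 849
sensor:
  r: spectra/sensor_r.csv
  g: spectra/sensor_g.csv
  b: spectra/sensor_b.csv
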
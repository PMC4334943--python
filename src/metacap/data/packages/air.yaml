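# Standalone environmental package: attachable to any template whose
# vocabularies it references (this one needs none beyond the core).
package:
  name: ep
  subtype: air
  fields:
    - key: sample_name
      label: Sample Name
      type: text
      required: true
      definition: Id of the sample this block describes.
    - key: altitude
      label: Altitude
      type: decimal
      required: true
      units: m
    - key: temperature
      label: Temperature
      type: decimal
      units: "°C"
    - key: humidity
      label: Relative Humidity
      type: decimal
      units: "%"
    - key: wind_speed
      label: Wind Speed
      type: decimal
      units: m/s
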
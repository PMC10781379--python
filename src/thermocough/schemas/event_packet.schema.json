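{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SensorEventPacket",
  "description": "Telemetry record emitted by a monitoring device: a fever reading or a detected cough with its audio evidence.",
  "type": "object",
  "properties": {
    "id": {
      "type": "string",
      "pattern": "^.+-[0-9A-F]{4}$",
      "description": "Device identity: common name plus the last four hex digits of the MAC address."
    },
    "time": {
      "type": "integer",
      "minimum": 0,
      "description": "Event time, integer epoch seconds."
    },
    "type": {
      "enum": ["thermal", "cough"]
    },
    "temperature": {
      "type": "number",
      "description": "Corrected patient temperature in degrees Celsius; present only on thermal packets."
    },
    "audio": {
      "type": "string",
      "description": "Base64-encoded 16-bit/16 kHz mono WAV bytes; present only on cough packets."
    }
  },
  "required": ["id", "time", "type"],
  "oneOf": [
    {
      "properties": {"type": {"const": "thermal"}},
      "required": ["temperature"],
      "not": {"required": ["audio"]}
    },
    {
      "properties": {"type": {"const": "cough"}},
      "required": ["audio"],
      "not": {"required": ["temperature"]}
    }
  ],
  "additionalProperties": false
}
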
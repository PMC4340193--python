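{
  "$defs": {
    "_InstanceDoc": {
      "additionalProperties": false,
      "properties": {
        "class": {
          "title": "Class",
          "type": "string"
        },
        "id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "integer"
            }
          ],
          "title": "Id"
        },
        "values": {
          "additionalProperties": true,
          "default": {},
          "title": "Values",
          "type": "object"
        }
      },
      "required": [
        "class",
        "id"
      ],
      "title": "_InstanceDoc",
      "type": "object"
    }
  },
  "items": {
    "$ref": "#/$defs/_InstanceDoc"
  },
  "title": "_InstancesDoc",
  "type": "array"
}
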
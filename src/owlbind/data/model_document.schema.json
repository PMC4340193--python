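{
  "$defs": {
    "_AnnotationDoc": {
      "additionalProperties": false,
      "properties": {
        "marker": {
          "title": "Marker",
          "type": "string"
        },
        "resource": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Resource"
        },
        "number": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Number"
        },
        "string_values": {
          "anyOf": [
            {
              "items": {
                "type": "string"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "String Values"
        }
      },
      "required": [
        "marker"
      ],
      "title": "_AnnotationDoc",
      "type": "object"
    },
    "_ClassDoc": {
      "additionalProperties": false,
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "package": {
          "title": "Package",
          "type": "string"
        },
        "extends": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Extends"
        },
        "enum": {
          "anyOf": [
            {
              "items": {
                "type": "string"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Enum"
        },
        "fields": {
          "default": [],
          "items": {
            "$ref": "#/$defs/_FieldDoc"
          },
          "title": "Fields",
          "type": "array"
        },
        "annotations": {
          "default": [],
          "items": {
            "$ref": "#/$defs/_AnnotationDoc"
          },
          "title": "Annotations",
          "type": "array"
        }
      },
      "required": [
        "name",
        "package"
      ],
      "title": "_ClassDoc",
      "type": "object"
    },
    "_FieldDoc": {
      "additionalProperties": false,
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "type": {
          "title": "Type",
          "type": "string"
        },
        "collection": {
          "default": false,
          "title": "Collection",
          "type": "boolean"
        },
        "id": {
          "default": false,
          "title": "Id",
          "type": "boolean"
        },
        "annotations": {
          "default": [],
          "items": {
            "$ref": "#/$defs/_AnnotationDoc"
          },
          "title": "Annotations",
          "type": "array"
        }
      },
      "required": [
        "name",
        "type"
      ],
      "title": "_FieldDoc",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "classes": {
      "items": {
        "$ref": "#/$defs/_ClassDoc"
      },
      "title": "Classes",
      "type": "array"
    }
  },
  "required": [
    "classes"
  ],
  "title": "_ModelDoc",
  "type": "object"
}
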